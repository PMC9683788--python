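"""Core in-memory containers for repertoire data.

A *clonotype* here is a unique nucleotide-level rearrangement: one
(V gene, CDR3 nucleotide sequence) pair observed in one sample, with a
template/read count.  A :class:`Repertoire` holds all clonotypes of one
sample, aggregated so that no two records share the (v_gene, cdr3_nt) key.
Convergence analysis then asks how many distinct nucleotide clonotypes
encode the same amino-acid-level receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import DataError

#: canonical column order of the records table
RECORD_COLUMNS = ["v_gene", "cdr3_nt", "cdr3_aa", "j_gene", "count"]


def normalize_v_gene(name: str, level: str = "gene") -> str:
    """Normalize a V-segment name for grouping.

    Allele suffixes (text after ``*``) are always stripped.  At
    ``level="family"`` the gene number after ``-`` is stripped as well
    (``TRBV20-1`` -> ``TRBV20``); the default is gene-level resolution.
    """
    name = str(name).strip()
    name = name.split("*", 1)[0]
    if level == "family":
        name = name.split("-", 1)[0].split("/", 1)[0]
    elif level != "gene":
        raise ValueError(f"unknown V-gene resolution level: {level!r}")
    return name


@dataclass(frozen=True)
class ClonotypeRecord:
    """One nucleotide-level rearrangement observation."""

    sample_id: str
    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: Optional[str] = None
    count: int = 1
    frequency: Optional[float] = None

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class PairedCellRecord:
    """A single T cell with its productive beta chain and, when captured,
    the best-supported productive alpha chain."""

    barcode: str
    beta: ClonotypeRecord
    alpha: Optional[ClonotypeRecord] = None


@dataclass
class Repertoire:
    """All clonotypes of one sample.

    ``records`` is a DataFrame with columns ``v_gene, cdr3_nt, cdr3_aa,
    j_gene, count``, one row per unique (v_gene, cdr3_nt) key, sorted
    canonically.  ``qc_applied`` records whether the CDR3 quality filter
    has been run; downstream convergence grouping refuses unfiltered input.
    """

    sample_id: str
    records: pd.DataFrame = field(repr=False)
    qc_applied: bool = False

    @property
    def n_clonotypes(self) -> int:
        """n — number of unique nucleotide-level clonotypes."""
        return len(self.records)

    @property
    def total_reads(self) -> int:
        """N — total template/read count across clonotypes."""
        return int(self.records["count"].sum()) if len(self.records) else 0

    @classmethod
    def from_frame(
        cls,
        sample_id: str,
        frame: pd.DataFrame,
        qc_applied: bool = False,
    ) -> "Repertoire":
        """Build a repertoire from a raw records table.

        Rows sharing (v_gene, cdr3_nt) are aggregated by summing counts.
        Rows with an empty CDR3 amino-acid sequence are dropped.  A key
        reported with two conflicting amino-acid translations is data
        corruption and raises :class:`DataError`.
        """
        df = frame.copy()
        for col in RECORD_COLUMNS:
            if col not in df.columns:
                if col == "j_gene":
                    df[col] = None
                else:
                    raise DataError(f"records table lacks column {col!r}")
        df = df[RECORD_COLUMNS]
        df["cdr3_aa"] = df["cdr3_aa"].fillna("").astype(str)
        df = df[df["cdr3_aa"].str.len() > 0]
        df["cdr3_nt"] = df["cdr3_nt"].astype(str).str.upper()
        df["count"] = df["count"].fillna(0).astype(int)
        if (df["count"] < 0).any():
            raise DataError("negative counts in records table")

        conflicts = df.groupby(["v_gene", "cdr3_nt"])["cdr3_aa"].nunique()
        bad = conflicts[conflicts > 1]
        if len(bad):
            key = bad.index[0]
            raise DataError(
                f"conflicting cdr3_aa for rearrangement {key}: "
                "identical (v_gene, cdr3_nt) must translate identically"
            )
        agg = (
            df.groupby(["v_gene", "cdr3_nt"], as_index=False)
            .agg(
                cdr3_aa=("cdr3_aa", "first"),
                j_gene=("j_gene", "first"),
                count=("count", "sum"),
            )
            .sort_values(["v_gene", "cdr3_nt"], kind="mergesort")
            .reset_index(drop=True)
        )
        return cls(sample_id=sample_id, records=agg[RECORD_COLUMNS], qc_applied=qc_applied)

    def to_records(self) -> list[ClonotypeRecord]:
        """Materialize rows as :class:`ClonotypeRecord` objects."""
        n_total = self.total_reads
        out = []
        for row in self.records.itertuples(index=False):
            out.append(
                ClonotypeRecord(
                    sample_id=self.sample_id,
                    cdr3_nt=row.cdr3_nt,
                    cdr3_aa=row.cdr3_aa,
                    v_gene=row.v_gene,
                    j_gene=row.j_gene,
                    count=int(row.count),
                    frequency=(row.count / n_total) if n_total else None,
                )
            )
        return out
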