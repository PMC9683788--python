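"""Readers and writers for the repertoire table dialects in common use.

Bulk TCRbeta repertoires come as immunoSEQ-style exports (column names vary
by vintage) or AIRR Rearrangement TSVs; single-cell V(D)J output comes as a
10x ``filtered_contig_annotations.csv``.  All readers normalize V-gene
names (allele suffixes stripped) and aggregate to unique (v_gene, cdr3_nt)
keys so downstream modules see one canonical representation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq

from .errors import FormatError, FrameError
from .repertoire import ClonotypeRecord, PairedCellRecord, Repertoire, normalize_v_gene

logger = logging.getLogger(__name__)

# Column synonym tables per dialect; first match wins.  Unknown extra
# columns are ignored.  immunoSEQ exports renamed their columns across
# platform vintages, hence the long synonym lists.
DIALECTS = {
    "immunoseq": {
        "cdr3_nt": ["nucleotide", "rearrangement", "nucleotide_sequence", "cdr3_rearrangement"],
        "cdr3_aa": ["aminoAcid", "amino_acid", "aa_sequence", "cdr3_amino_acid"],
        "v_gene": ["vGeneName", "v_gene", "vGene", "v_resolved", "vMaxResolved"],
        "j_gene": ["jGeneName", "j_gene", "jGene", "j_resolved", "jMaxResolved"],
        "count": ["count (templates/reads)", "templates", "reads", "count", "count (reads)"],
    },
    "airr": {
        "cdr3_nt": ["junction"],
        "cdr3_aa": ["junction_aa"],
        "v_gene": ["v_call"],
        "j_gene": ["j_call"],
        "count": ["duplicate_count"],
    },
}

_REQUIRED = ("cdr3_nt", "cdr3_aa", "v_gene", "count")

#: characters accepted in a CDR3 nucleotide sequence
DNA_ALPHABET = frozenset("ACGT")


def _resolve_columns(columns: Iterable[str], dialect: str) -> dict:
    if dialect not in DIALECTS:
        raise FormatError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}"
        )
    synonyms = DIALECTS[dialect]
    available = list(columns)
    mapping = {}
    for field, names in synonyms.items():
        found = next((n for n in names if n in available), None)
        if found is None and field in _REQUIRED:
            raise FormatError(
                f"{dialect} table lacks required column {names[0]!r} "
                f"(accepted synonyms: {names})"
            )
        if found is not None:
            mapping[field] = found
    return mapping


def read_bulk_tsv(
    path,
    dialect: str = "immunoseq",
    sample_id: Optional[str] = None,
    v_gene_level: str = "gene",
) -> Repertoire:
    """Read a bulk TCRbeta repertoire TSV into a :class:`Repertoire`.

    Duplicate (v_gene, cdr3_nt) rows are aggregated by summing counts;
    rows with an empty CDR3 amino-acid sequence are dropped.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    mapping = _resolve_columns(raw.columns, dialect)
    df = pd.DataFrame(
        {
            "v_gene": raw[mapping["v_gene"]],
            "cdr3_nt": raw[mapping["cdr3_nt"]],
            "cdr3_aa": raw[mapping["cdr3_aa"]],
            "j_gene": raw[mapping["j_gene"]] if "j_gene" in mapping else None,
            "count": pd.to_numeric(raw[mapping["count"]], errors="coerce").fillna(0),
        }
    )
    df = df[df["v_gene"].notna()]
    df["v_gene"] = df["v_gene"].map(lambda v: normalize_v_gene(v, v_gene_level))
    return Repertoire.from_frame(sample_id or path.stem, df)


def read_10x_contigs(path, sample_id: Optional[str] = None):
    """Read a 10x filtered contig table and pair alpha/beta chains per cell.

    Returns ``(cells, qc_report)`` where *cells* is a list of
    :class:`PairedCellRecord`.  Only productive contigs are considered; a
    cell is retained iff it has exactly one productive beta chain
    (ambiguous multi-beta cells would corrupt degeneracy counts and are
    dropped, counted in the report).  When several productive alphas are
    present the one with the highest supporting read count is attached.
    """
    path = Path(path)
    required = {"barcode", "chain", "v_gene", "cdr3", "cdr3_nt", "productive"}
    try:
        raw = pd.read_csv(path, dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"contig table lacks required column(s) {sorted(missing)}")
    sid = sample_id or path.stem

    productive = raw[raw["productive"].str.lower().isin({"true", "t", "yes"})].copy()
    productive["reads"] = pd.to_numeric(productive.get("reads"), errors="coerce").fillna(0)
    betas = productive[productive["chain"] == "TRB"]
    alphas = productive[productive["chain"] == "TRA"]
    if betas.empty:
        logger.warning("no productive beta contigs in %s", path)

    report = {"n_barcodes": raw["barcode"].nunique(), "no_beta": 0, "multi_beta": 0, "paired": 0, "beta_only": 0}
    cells: list[PairedCellRecord] = []
    beta_groups = {bc: grp for bc, grp in betas.groupby("barcode")}
    alpha_groups = {bc: grp for bc, grp in alphas.groupby("barcode")}
    for bc in sorted(raw["barcode"].unique()):
        bgrp = beta_groups.get(bc)
        if bgrp is None or len(bgrp) == 0:
            report["no_beta"] += 1
            continue
        if len(bgrp) > 1:
            report["multi_beta"] += 1
            continue
        brow = bgrp.iloc[0]
        beta = ClonotypeRecord(
            sample_id=sid,
            cdr3_nt=str(brow["cdr3_nt"]).upper(),
            cdr3_aa=str(brow["cdr3"]),
            v_gene=normalize_v_gene(brow["v_gene"]),
            count=1,
        )
        agrp = alpha_groups.get(bc)
        alpha = None
        if agrp is not None and len(agrp):
            arow = agrp.sort_values(["reads", "cdr3_nt"], ascending=[False, True]).iloc[0]
            alpha = ClonotypeRecord(
                sample_id=sid,
                cdr3_nt=str(arow["cdr3_nt"]).upper(),
                cdr3_aa=str(arow["cdr3"]),
                v_gene=normalize_v_gene(arow["v_gene"]),
                count=1,
            )
            report["paired"] += 1
        else:
            report["beta_only"] += 1
        cells.append(PairedCellRecord(barcode=bc, beta=beta, alpha=alpha))
    return cells, report


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate a CDR3 nucleotide sequence under the standard genetic code.

    Raises :class:`FrameError` if the length is not a multiple of three or
    the sequence contains non-ACGT characters.  Stop codons translate to
    ``*``; use :func:`is_productive` to flag them.
    """
    seq = str(cdr3_nt).upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"CDR3 length {len(seq)} is not a multiple of 3")
    if not set(seq) <= DNA_ALPHABET:
        raise FrameError(f"non-ACGT characters in CDR3: {seq!r}")
    return str(Seq(seq).translate())


def is_productive(cdr3_nt: str) -> bool:
    """True iff the in-frame translation contains no stop codon."""
    return "*" not in translate_cdr3(cdr3_nt)


# immunoSEQ-style columns used when writing repertoires back out
_WRITE_COLUMNS = {
    "cdr3_nt": "nucleotide",
    "cdr3_aa": "aminoAcid",
    "v_gene": "vGeneName",
    "j_gene": "jGeneName",
    "count": "count (templates/reads)",
}


def write_repertoire(rep: Repertoire, path) -> None:
    """Write a repertoire as an immunoSEQ-dialect TSV (bit-stable order)."""
    df = rep.records.rename(columns=_WRITE_COLUMNS)
    df = df.sort_values(["vGeneName", "nucleotide"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_report(frame: pd.DataFrame, path, sort_by: Optional[list] = None) -> None:
    """Write any tabular module output as a TSV with deterministic ordering.

    Rows are sorted by *sort_by* (default: all non-numeric key columns in
    order) so that identical inputs produce byte-identical files.
    """
    df = frame.copy()
    if sort_by is None:
        sort_by = [c for c in df.columns if df[c].dtype == object] or list(df.columns)
    if len(df):
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
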