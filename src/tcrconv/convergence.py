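"""TCR convergence: the core statistic.

Clonotypes with identical CDR3 amino-acid sequence and V gene but distinct
CDR3 nucleotide sequences within one sample are *convergent*: several
independent rearrangements converged on the same receptor protein.  The
*degeneracy* of an amino-acid-level TCR is the number of distinct
nucleotide clonotypes encoding it in that sample; degeneracy 1 means
non-convergent, >= 2 convergent.  Degeneracy is always computed within a
single sample — pooling samples would conflate convergence with publicity
(sharing across individuals), which is a different biological process.

Grouping operates on a QC-filtered :class:`~tcrconv.repertoire.Repertoire`
(bulk beta-chain mode) or on paired single-cell records, where the grouping
key concatenates the beta and alpha (V gene, CDR3 aa) pairs and degeneracy
counts distinct (beta nt, alpha nt) combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import binomtest

from .errors import ConfigurationError, ParameterError, UndefinedStatisticError
from .qc import AA20, DEFAULT_POLICY, passes_qc
from .repertoire import PairedCellRecord, Repertoire, normalize_v_gene

#: number of CDR3 residues stripped from each end for composition analysis;
#: the first/last three positions are dictated by the V/J germline segments
EDGE_STRIP = 3

GROUP_COLUMNS = ["v_gene", "cdr3_aa", "degeneracy", "n_variants", "total_count", "variants"]


def compute_groups(
    rep: Repertoire,
    mode: str = "bulk_beta",
    include_j: bool = False,
) -> pd.DataFrame:
    """Partition a repertoire into amino-acid-level TCR groups.

    Returns a DataFrame with one row per (v_gene, cdr3_aa) key (plus
    j_gene when ``include_j``), carrying the distinct nucleotide variants,
    their number (``degeneracy`` == ``n_variants``) and the summed read
    count.  Refuses repertoires that have not passed QC.
    """
    if mode != "bulk_beta":
        raise ParameterError(
            "compute_groups handles mode='bulk_beta'; use compute_paired_groups "
            "for paired single-cell data"
        )
    if not rep.qc_applied:
        raise ConfigurationError(
            f"repertoire {rep.sample_id!r} has not been QC-filtered; "
            "run tcrconv.qc.filter_repertoire first"
        )
    key_cols = ["v_gene", "cdr3_aa"] + (["j_gene"] if include_j else [])
    if not len(rep.records):
        out = pd.DataFrame(columns=key_cols + ["degeneracy", "n_variants", "total_count", "variants"])
    else:
        out = (
            rep.records.groupby(key_cols, as_index=False, dropna=False)
            .agg(
                degeneracy=("cdr3_nt", "nunique"),
                total_count=("count", "sum"),
                variants=("cdr3_nt", lambda s: tuple(sorted(set(s)))),
            )
            .sort_values(key_cols, kind="mergesort")
            .reset_index(drop=True)
        )
        out.insert(out.columns.get_loc("degeneracy") + 1, "n_variants", out["degeneracy"])
    out.attrs["sample_id"] = rep.sample_id
    out.attrs["key_columns"] = key_cols
    out.attrs["mode"] = mode
    return out


def compute_paired_groups(
    cells: Sequence[PairedCellRecord],
    policy=DEFAULT_POLICY,
) -> pd.DataFrame:
    """Group paired single-cell TCRs at the amino-acid level.

    The key is the concatenation of beta and alpha (V gene, CDR3 aa);
    degeneracy counts distinct (beta nt, alpha nt) combinations.  Cells
    whose beta CDR3 (or alpha CDR3, when present) fails QC are dropped.
    ``total_count`` is the number of cells in the group.
    """
    rows = []
    for cell in cells:
        if not passes_qc(cell.beta.cdr3_aa, policy):
            continue
        if cell.alpha is not None and not passes_qc(cell.alpha.cdr3_aa, policy):
            continue
        rows.append(
            {
                "v_gene": cell.beta.v_gene,
                "cdr3_aa": cell.beta.cdr3_aa,
                "alpha_v_gene": cell.alpha.v_gene if cell.alpha else "",
                "alpha_cdr3_aa": cell.alpha.cdr3_aa if cell.alpha else "",
                "nt_pair": (cell.beta.cdr3_nt, cell.alpha.cdr3_nt if cell.alpha else ""),
            }
        )
    key_cols = ["v_gene", "cdr3_aa", "alpha_v_gene", "alpha_cdr3_aa"]
    if not rows:
        out = pd.DataFrame(columns=key_cols + ["degeneracy", "n_variants", "total_count", "variants"])
    else:
        df = pd.DataFrame(rows)
        out = (
            df.groupby(key_cols, as_index=False)
            .agg(
                degeneracy=("nt_pair", "nunique"),
                total_count=("nt_pair", "size"),
                variants=("nt_pair", lambda s: tuple(sorted(set(s)))),
            )
            .sort_values(key_cols, kind="mergesort")
            .reset_index(drop=True)
        )
        out.insert(out.columns.get_loc("degeneracy") + 1, "n_variants", out["degeneracy"])
    out.attrs["key_columns"] = key_cols
    out.attrs["mode"] = "paired_sc"
    return out


def group_keys(groups: pd.DataFrame) -> list[tuple]:
    key_cols = groups.attrs.get("key_columns", ["v_gene", "cdr3_aa"])
    return list(map(tuple, groups[key_cols].itertuples(index=False, name=None)))


def convergent_set(groups: pd.DataFrame) -> set[tuple]:
    """Keys of all convergent groups (degeneracy >= 2)."""
    key_cols = groups.attrs.get("key_columns", ["v_gene", "cdr3_aa"])
    conv = groups[groups["degeneracy"] >= 2]
    return set(map(tuple, conv[key_cols].itertuples(index=False, name=None)))


def convergence_summary(groups: pd.DataFrame) -> dict:
    """Convergence level and fractions for one sample.

    ``convergence_level`` is the count of convergent groups (the statistic
    used for prognostic stratification); ``convergent_clone_fraction`` is
    that count over the number of amino-acid-level groups;
    ``convergent_cell_fraction`` weights by cells/reads.
    """
    n_groups = len(groups)
    conv = groups[groups["degeneracy"] >= 2]
    level = len(conv)
    total = groups["total_count"].sum() if n_groups else 0
    return {
        "n_groups": int(n_groups),
        "convergence_level": int(level),
        "convergent_clone_fraction": (level / n_groups) if n_groups else float("nan"),
        "convergent_cell_fraction": (conv["total_count"].sum() / total) if total else float("nan"),
    }


@dataclass
class DegeneracySpectrum:
    """Histogram of group degeneracies for one sample."""

    counts: dict = field(default_factory=dict)  # degeneracy d -> number of groups
    convergent_shares: dict = field(default_factory=dict)  # d>=2 -> fraction of convergent groups

    @property
    def n_groups(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clonotypes(self) -> int:
        return sum(d * c for d, c in self.counts.items())


def degeneracy_spectrum(groups: pd.DataFrame) -> DegeneracySpectrum:
    """Exact histogram of degeneracies, plus each convergent class's share
    of all convergent groups."""
    if not len(groups):
        return DegeneracySpectrum()
    counts = groups["degeneracy"].value_counts().sort_index()
    spectrum = {int(d): int(c) for d, c in counts.items()}
    n_conv = sum(c for d, c in spectrum.items() if d >= 2)
    shares = {d: c / n_conv for d, c in spectrum.items() if d >= 2} if n_conv else {}
    return DegeneracySpectrum(counts=spectrum, convergent_shares=shares)


def length_and_vgene_profiles(groups: pd.DataFrame) -> dict:
    """Per-CDR3-length and per-V-gene/family profiles.

    For each stratum: group count, convergent-group count, and mean
    degeneracy.  All counts are over unique amino-acid-level TCRs.
    """
    out = {}
    if not len(groups):
        empty = pd.DataFrame(columns=["n_groups", "n_convergent", "mean_degeneracy"])
        return {"length": empty, "v_gene": empty.copy(), "v_family": empty.copy()}
    work = groups.assign(
        length=groups["cdr3_aa"].str.len(),
        convergent=groups["degeneracy"] >= 2,
        v_family=groups["v_gene"].map(lambda v: normalize_v_gene(v, "family")),
    )
    for name, col in (("length", "length"), ("v_gene", "v_gene"), ("v_family", "v_family")):
        prof = work.groupby(col).agg(
            n_groups=("degeneracy", "size"),
            n_convergent=("convergent", "sum"),
            mean_degeneracy=("degeneracy", "mean"),
        )
        prof["n_convergent"] = prof["n_convergent"].astype(int)
        out[name] = prof.sort_index()
    return out


@dataclass
class AAComposition:
    """Pooled interior amino-acid composition of one degeneracy class.

    Each group contributes once (unique-TCR weighting, not read-weighted);
    the first and last three CDR3 residues are excluded because they are
    templated by the V/J segments rather than junctional.
    """

    degeneracy: int
    counts: pd.Series  # residue -> pooled interior count
    total: int  # pooled interior residues
    n_groups: int
    n_skipped: int  # groups too short to have an interior

    @property
    def proportions(self) -> pd.Series:
        if self.total == 0:
            return self.counts.astype(float)
        return self.counts / self.total


def aa_composition(groups: pd.DataFrame, degeneracy: int) -> AAComposition:
    """Interior amino-acid composition of groups with the given degeneracy.

    Sequences shorter than ``2 * EDGE_STRIP + 1`` residues have no interior
    and are skipped (counted).  Under the default QC minimum length of 8
    every group has an interior of at least 2 residues.
    """
    sel = groups[groups["degeneracy"] == degeneracy]
    counts = pd.Series(0, index=sorted(AA20), dtype=int)
    n_skipped = 0
    for seq in sel["cdr3_aa"]:
        interior = seq[EDGE_STRIP:-EDGE_STRIP]
        if not interior:
            n_skipped += 1
            continue
        for ch in interior:
            counts[ch] += 1
    comp = AAComposition(
        degeneracy=degeneracy,
        counts=counts,
        total=int(counts.sum()),
        n_groups=len(sel),
        n_skipped=n_skipped,
    )
    return comp


def aa_enrichment_test(
    composition: AAComposition,
    baseline: AAComposition,
    amino_acid: str,
) -> float:
    """Two-sided exact binomial test for one residue's usage shift.

    Tests whether the pooled interior count of *amino_acid* in
    *composition* (k successes out of m residues) is compatible with the
    baseline class's proportion p0 — the exact two-sided p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if composition.total == 0:
        raise UndefinedStatisticError("no interior residues in the tested class")
    p0 = float(baseline.proportions.get(amino_acid, 0.0))
    if not (0.0 < p0 < 1.0):
        raise ParameterError(f"baseline proportion for {amino_acid!r} must lie in (0,1)")
    k = int(composition.counts.get(amino_acid, 0))
    return float(binomtest(k, composition.total, p0, alternative="two-sided").pvalue)


def exact_binomial_pvalue(k: int, m: int, p0: float) -> float:
    """Two-sided exact binomial p-value for k successes in m trials at p0."""
    if m <= 0:
        raise UndefinedStatisticError("zero trials")
    if not (0.0 < p0 < 1.0):
        raise ParameterError("p0 must lie in (0,1)")
    return float(binomtest(int(k), int(m), p0, alternative="two-sided").pvalue)
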