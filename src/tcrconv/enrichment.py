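"""Association between a TCR set and an antigen-specificity label set.

Over the universe of one sample's unique amino-acid-level TCRs, a 2x2
contingency table crosses membership in a TCR set (convergent TCRs, or the
matched top-k expanded TCRs) with membership in a label set
(multimer-positive / antigen-specific / cluster membership).  Inference is
Fisher's exact test; the effect size reported is the sample odds ratio
(a*d)/(b*c) with a Haldane-Anscombe +0.5 correction on all cells when any
cell is zero.  The matched-expansion comparator selects the k
highest-count groups with k equal to the number of convergent groups, so
convergence and expansion are compared at identical set sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .convergence import convergent_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """a = set∩label, b = set\\label, c = label\\set, d = neither."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    continuity_corrected: bool

    @property
    def log10_odds_ratio(self) -> float:
        return math.log10(self.odds_ratio)


def _sample_odds_ratio(t: ContingencyTable) -> tuple[float, bool]:
    if min(t.a, t.b, t.c, t.d) == 0:
        a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
        return (a * d) / (b * c), True
    return (t.a * t.d) / (t.b * t.c), False


def fisher_test_table(table: ContingencyTable) -> EnrichmentResult:
    """Exact two-sided Fisher test plus sample odds ratio for a 2x2 table."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    odds, corrected = _sample_odds_ratio(table)
    return EnrichmentResult(
        table=table, odds_ratio=float(odds), p_value=float(p), continuity_corrected=corrected
    )


def fisher_enrichment(
    set_keys: Iterable, label_keys: Iterable, universe_keys: Iterable
) -> EnrichmentResult:
    """Fisher's exact association of a TCR set with a label set.

    Both sets must be subsets of the universe of unique TCR keys in the
    sample.  Returns the exact two-sided p-value (hypergeometric: sum of
    the probabilities of all tables with the observed margins no more
    probable than the observed table) and the sample odds ratio.
    """
    universe = set(universe_keys)
    if not universe:
        raise ParameterError("empty universe")
    s, l = set(set_keys), set(label_keys)
    if not s <= universe or not l <= universe:
        raise ParameterError("set and label keys must be subsets of the universe")
    a = len(s & l)
    b = len(s - l)
    c = len(l - s)
    d = len(universe) - a - b - c
    return fisher_test_table(ContingencyTable(a, b, c, d))


def select_expanded(groups: pd.DataFrame, k: int) -> set[tuple]:
    """The k amino-acid-level groups with the highest read counts.

    Ties at the k-th rank are broken deterministically: higher total
    count first, then lexicographic (v_gene, cdr3_aa).  If k exceeds the
    number of groups, all groups are returned with a warning.
    """
    if k < 0:
        raise ParameterError("k must be non-negative")
    key_cols = groups.attrs.get("key_columns", ["v_gene", "cdr3_aa"])
    if k > len(groups):
        logger.warning("k=%d exceeds the %d available groups; taking all", k, len(groups))
        k = len(groups)
    ranked = groups.sort_values(
        ["total_count"] + key_cols, ascending=[False] + [True] * len(key_cols), kind="mergesort"
    ).head(k)
    return set(map(tuple, ranked[key_cols].itertuples(index=False, name=None)))


def convergence_vs_expansion(
    samples: Mapping[str, tuple[pd.DataFrame, Iterable]],
) -> tuple[pd.DataFrame, dict]:
    """Paired convergence-vs-expansion enrichment across samples.

    *samples* maps sample_id -> (groups table, label keys).  For each
    sample the convergent set and the count-matched expanded set (k =
    number of convergent groups) are tested against the labels over the
    sample's universe of unique TCRs.  Samples without convergent groups
    are excluded from the pairing and listed in the summary.  The summary
    reports mean odds ratios, the mean paired difference of log10 odds
    ratios, and a Welch two-sample t-test on the log10 odds ratios.
    """
    rows = []
    skipped = []
    for sid, (groups, labels) in samples.items():
        key_cols = groups.attrs.get("key_columns", ["v_gene", "cdr3_aa"])
        universe = set(map(tuple, groups[key_cols].itertuples(index=False, name=None)))
        conv = convergent_set(groups)
        if not conv:
            skipped.append(sid)
            logger.info("sample %s has no convergent TCRs; excluded from pairing", sid)
            continue
        labels = set(labels) & universe
        res_conv = fisher_enrichment(conv, labels, universe)
        expanded = select_expanded(groups, k=len(conv))
        res_exp = fisher_enrichment(expanded, labels, universe)
        rows.append(
            {
                "sample_id": sid,
                "n_universe": len(universe),
                "n_convergent": len(conv),
                "n_labels": len(labels),
                "or_convergence": res_conv.odds_ratio,
                "p_convergence": res_conv.p_value,
                "or_expansion": res_exp.odds_ratio,
                "p_expansion": res_exp.p_value,
                "delta_log10_or": res_conv.log10_odds_ratio - res_exp.log10_odds_ratio,
            }
        )
    table = pd.DataFrame(rows)
    summary: dict = {"n_samples": len(table), "skipped_samples": skipped}
    if len(table):
        summary["mean_or_convergence"] = float(table["or_convergence"].mean())
        summary["mean_or_expansion"] = float(table["or_expansion"].mean())
        summary["mean_delta_log10_or"] = float(table["delta_log10_or"].mean())
        if len(table) >= 2:
            welch = stats.ttest_ind(
                np.log10(table["or_convergence"]),
                np.log10(table["or_expansion"]),
                equal_var=False,
            )
            summary["welch_t_p_value"] = float(welch.pvalue)
    return table, summary
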