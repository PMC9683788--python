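"""Prognostic stratification by convergence level.

A sample's *convergence level* is the number of convergent amino-acid
TCR groups it contains.  Samples are split at the cohort median (above ->
"high", below -> "low"; values exactly at the median are assigned high
and reported as ties).  The survival machinery itself — Kaplan-Meier,
log-rank, multivariate Cox — is delegated to lifelines; the bespoke part
is the stratifying statistic and the assembly of the analysis table with
its fixed covariate set: clonality, diversity, treatment and sequencing
depth (total detected clonotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import DataError, ParameterError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: covariates adjusted for in the multivariate Cox model, besides the
#: convergence group itself
COX_COVARIATES = ("clonality", "diversity", "treatment", "total_clonotypes")


@dataclass
class StratificationResult:
    labels: dict  # sample_id -> "high" | "low"
    median: float
    ties: list = field(default_factory=list)  # sample_ids at the median, assigned high


def stratify_by_median(levels: Mapping[str, float]) -> StratificationResult:
    """Median split of convergence levels into high/low groups.

    The median uses the midpoint convention for even sample counts.
    Samples exactly at the median are assigned "high" and reported in
    ``ties`` (a deterministic, visible rule — the alternative of dropping
    them would silently shrink the cohort).  A cohort in which every
    level is identical cannot be stratified and is refused.
    """
    if len(levels) < 2:
        raise ParameterError("stratification needs at least 2 samples")
    values = np.array(list(levels.values()), dtype=float)
    if np.all(values == values[0]):
        raise UndefinedStatisticError("all convergence levels identical; cannot stratify")
    median = float(np.median(values))
    labels = {}
    ties = []
    for sid, lvl in levels.items():
        if lvl == median:
            ties.append(sid)
            labels[sid] = "high"
        else:
            labels[sid] = "high" if lvl > median else "low"
    if ties:
        logger.warning("%d sample(s) at the median level assigned to 'high': %s", len(ties), ties)
    return StratificationResult(labels=labels, median=median, ties=ties)


def build_survival_table(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    time_col: str = "os_days",
    event_col: str = "os_event",
    allow_partial: bool = False,
) -> pd.DataFrame:
    """Join per-sample repertoire summaries with clinical outcomes.

    *summaries* needs sample_id, convergence_level, clonality, diversity,
    total_clonotypes; *clinical* needs sample_id, the time and event
    columns, and treatment.  The join must be 1:1; unmatched ids abort
    the run (named in the error) unless ``allow_partial``.  The returned
    table carries exactly the group label and the four Cox covariates —
    no silent extras.
    """
    for col in ("sample_id", "convergence_level", "clonality", "diversity", "total_clonotypes"):
        if col not in summaries.columns:
            raise DataError(f"summaries table lacks column {col!r}")
    for col in ("sample_id", time_col, event_col, "treatment"):
        if col not in clinical.columns:
            raise DataError(f"clinical table lacks column {col!r}")
    s_ids = set(summaries["sample_id"])
    c_ids = set(clinical["sample_id"])
    if len(s_ids) != len(summaries) or len(c_ids) != len(clinical):
        raise DataError("duplicate sample_ids; the join must be 1:1")
    unmatched = sorted(s_ids ^ c_ids)
    if unmatched and not allow_partial:
        raise DataError(f"unmatched sample_ids: {unmatched}")

    merged = summaries.merge(
        clinical[["sample_id", time_col, event_col, "treatment"]], on="sample_id", how="inner"
    )
    strat = stratify_by_median(dict(zip(merged["sample_id"], merged["convergence_level"])))
    merged["group_label"] = merged["sample_id"].map(strat.labels)
    out = merged[
        ["sample_id", "group_label", "convergence_level", "clonality", "diversity",
         "treatment", "total_clonotypes", time_col, event_col]
    ].rename(columns={time_col: "time", event_col: "event"})
    out.attrs["median_level"] = strat.median
    out.attrs["ties"] = strat.ties
    return out.reset_index(drop=True)


def km_logrank(table: pd.DataFrame) -> dict:
    """Kaplan-Meier fits per convergence group and the log-rank p-value.

    Fitting is delegated to lifelines; outputs are passed through
    unmodified.
    """
    groups = {}
    for label, sub in table.groupby("group_label"):
        kmf = KaplanMeierFitter(label=label)
        kmf.fit(sub["time"], event_observed=sub["event"])
        groups[label] = kmf
    if set(groups) != {"high", "low"}:
        raise UndefinedStatisticError("log-rank needs both a high and a low group")
    high = table[table["group_label"] == "high"]
    low = table[table["group_label"] == "low"]
    lr = logrank_test(high["time"], low["time"], high["event"], low["event"])
    return {"fitters": groups, "logrank_p": float(lr.p_value), "test": lr}


def cox_multivariate(
    table: pd.DataFrame, covariates: Sequence[str] = COX_COVARIATES
) -> CoxPHFitter:
    """Multivariate Cox regression of outcome on convergence group plus
    the standard covariates (delegated to lifelines)."""
    df = table.copy()
    df["high_convergence"] = (df["group_label"] == "high").astype(int)
    cols = ["time", "event", "high_convergence"] + [c for c in covariates if c in df.columns]
    cph = CoxPHFitter()
    cph.fit(df[cols], duration_col="time", event_col="event")
    return cph
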