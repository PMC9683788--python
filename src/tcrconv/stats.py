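"""Repertoire clonality and diversity indices.

Clonality is one minus Pielou's evenness of the clone-size distribution:

    clonality = 1 + sum_i p_i * log2(p_i) / log2(n)

where p_i is the proportional abundance of nucleotide-level clonotype i
and n the number of clonotypes.  It is 0 for a perfectly even repertoire
and approaches 1 when a single clone dominates.  Diversity is n/N, the
number of clonotypes over the total read count.  Both indices are defined
over QC-passed nucleotide-level clonotypes, the unit the sequencer
reports; this is configurable but not the default for amino-acid groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .repertoire import Repertoire

logger = logging.getLogger(__name__)


def clonality(frequencies) -> float:
    """1 - Pielou's evenness of a frequency vector summing to 1.

    Zero entries are dropped (0*log 0 := 0) with a log message; fewer
    than two nonzero entries make the index undefined (log2(1) = 0) and
    raise :class:`UndefinedStatisticError`.  The result is clipped to
    [0, 1] against floating-point drift.
    """
    p = np.asarray(list(frequencies), dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    nz = p[p > 0]
    if len(nz) < len(p):
        logger.info("dropped %d zero frequencies before clonality", len(p) - len(nz))
    if abs(nz.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {nz.sum()!r})")
    n = len(nz)
    if n < 2:
        raise UndefinedStatisticError("clonality is undefined for fewer than 2 clonotypes")
    value = 1.0 + float(np.sum(nz * np.log2(nz))) / np.log2(n)
    return float(min(1.0, max(0.0, value)))


def clonality_from_counts(counts) -> float:
    """Clonality computed from raw clone counts (scale-invariant)."""
    c = np.asarray(list(counts), dtype=float)
    total = c[c > 0].sum()
    if total <= 0:
        raise UndefinedStatisticError("no positive counts")
    return clonality(c[c > 0] / total)


def diversity(n: int, N: int) -> float:
    """n/N: unique clonotypes per sequenced template."""
    if N <= 0:
        raise UndefinedStatisticError("diversity is undefined for zero total reads")
    if n < 1 or n > N:
        raise ValueError("need N >= n >= 1")
    return n / N


@dataclass(frozen=True)
class DiversityIndices:
    sample_id: str
    n: int
    N: int
    clonality: float
    diversity: float


def repertoire_indices(rep: Repertoire) -> DiversityIndices:
    """Clonality and diversity of one repertoire's clone-size distribution."""
    counts = rep.records.loc[rep.records["count"] > 0, "count"]
    n, N = len(counts), int(counts.sum())
    return DiversityIndices(
        sample_id=rep.sample_id,
        n=n,
        N=N,
        clonality=clonality_from_counts(counts),
        diversity=diversity(n, N),
    )
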