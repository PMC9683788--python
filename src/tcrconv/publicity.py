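"""Public TCRs and their overlap with convergence.

A TCR (amino-acid level: V gene + CDR3 aa) is *public* when it is found in
at least a given fraction of the individuals of a reference cohort — the
conventional threshold is 5%, which with a 666-donor reference cohort
means at least 34 individuals.  "At least 5%" is implemented as
``ceil(threshold * n_individuals)``, the convention that reproduces that
printed pair.  Publicity is a presence/absence notion: read counts play
no role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import ParameterError, UndefinedStatisticError
from .repertoire import Repertoire


def min_individuals(n_individuals: int, threshold: float) -> int:
    """Smallest individual count satisfying "shared by at least
    *threshold* of the cohort": ceil(threshold * n_individuals)."""
    if not (0.0 < threshold <= 1.0):
        raise ParameterError("sharing threshold must lie in (0, 1]")
    return math.ceil(threshold * n_individuals)


@dataclass(frozen=True)
class PublicSet:
    keys: frozenset  # (v_gene, cdr3_aa) tuples
    source_cohort_size: int
    sharing_threshold: float
    min_individuals: int

    def __contains__(self, key) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def derive_public_set(
    cohort: Mapping[str, Repertoire], threshold: float = 0.05
) -> PublicSet:
    """Derive the public TCR set from a cohort of repertoires.

    A (v_gene, cdr3_aa) key is public iff it is present (any count >= 1)
    in at least ``ceil(threshold * n_individuals)`` distinct individuals.
    """
    if len(cohort) < 2:
        raise ParameterError("a public set needs a cohort of at least 2 individuals")
    n_ind = len(cohort)
    need = min_individuals(n_ind, threshold)
    sharing: dict[tuple, int] = {}
    for rep in cohort.values():
        keys = set(
            map(tuple, rep.records[["v_gene", "cdr3_aa"]].itertuples(index=False, name=None))
        )
        for key in keys:
            sharing[key] = sharing.get(key, 0) + 1
    public = frozenset(k for k, c in sharing.items() if c >= need)
    return PublicSet(
        keys=public,
        source_cohort_size=n_ind,
        sharing_threshold=threshold,
        min_individuals=need,
    )


def public_fraction_of_convergent(convergent_keys, public: PublicSet) -> float:
    """Fraction of a sample's convergent TCRs that are public:
    |convergent ∩ public| / |convergent|."""
    convergent_keys = set(convergent_keys)
    if not convergent_keys:
        raise UndefinedStatisticError(
            "public fraction is undefined for an empty convergent set"
        )
    return len(convergent_keys & public.keys) / len(convergent_keys)
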