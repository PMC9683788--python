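"""CDR3 quality control.

A CDR3 amino-acid sequence passes QC iff it is 8-23 residues long
(inclusive), starts with cysteine, ends with phenylalanine, and uses only
the 20 standard amino acids.  The length window and the C...F anchor rule
remove truncated or mis-called junctions before any convergence analysis;
sequences containing ``*``, ``X`` or ``_`` are artefacts of out-of-frame
or ambiguous reads and are excluded by the alphabet rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .repertoire import Repertoire

logger = logging.getLogger(__name__)

#: the 20 standard amino acids
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: per-rule attribution order for records failing several rules
RULE_ORDER = ("alphabet", "length", "start", "end")


@dataclass(frozen=True)
class QCPolicy:
    min_len: int = 8
    max_len: int = 23
    required_start: str = "C"
    required_end: str = "F"

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


DEFAULT_POLICY = QCPolicy()


def failing_rule(cdr3_aa: str, policy: QCPolicy = DEFAULT_POLICY) -> Optional[str]:
    """Name of the first rule the sequence fails, or None if it passes.

    Rules are checked in the fixed order alphabet, length, start, end so
    that per-rule removal counts are deterministic.
    """
    if not cdr3_aa or not set(cdr3_aa) <= AA20:
        return "alphabet"
    if not (policy.min_len <= len(cdr3_aa) <= policy.max_len):
        return "length"
    if cdr3_aa[0] != policy.required_start:
        return "start"
    if cdr3_aa[-1] != policy.required_end:
        return "end"
    return None


def passes_qc(cdr3_aa: str, policy: QCPolicy = DEFAULT_POLICY) -> bool:
    """True iff the CDR3 amino-acid sequence satisfies every QC rule."""
    return failing_rule(cdr3_aa, policy) is None


@dataclass
class QCSummary:
    n_input: int
    n_retained: int
    removed: dict = field(default_factory=dict)  # rule -> count

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def filter_repertoire(
    rep: Repertoire, policy: QCPolicy = DEFAULT_POLICY
) -> tuple[Repertoire, QCSummary]:
    """Apply the CDR3 QC filter to a repertoire.

    Returns the filtered repertoire (``qc_applied`` set) and a summary
    attributing each removed clonotype to the first rule it failed.
    Filtering is idempotent.
    """
    rules = rep.records["cdr3_aa"].map(lambda s: failing_rule(s, policy))
    kept = rep.records[rules.isna()].reset_index(drop=True)
    removed = {rule: int((rules == rule).sum()) for rule in RULE_ORDER}
    summary = QCSummary(n_input=len(rep.records), n_retained=len(kept), removed=removed)
    if not len(kept):
        logger.warning("QC removed every clonotype of sample %s", rep.sample_id)
    return Repertoire(sample_id=rep.sample_id, records=kept, qc_applied=True), summary
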