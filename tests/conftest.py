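"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from tcrconv.repertoire import Repertoire
from tcrconv.simulate import CODONS_BY_AA

NONSTOP_CODONS = sorted({c for codons in CODONS_BY_AA.values() for c in codons})


def make_repertoire(rows, sample_id="s1", qc_applied=False) -> Repertoire:
    """Build a repertoire from (v_gene, cdr3_nt, cdr3_aa, count) tuples."""
    frame = pd.DataFrame(rows, columns=["v_gene", "cdr3_nt", "cdr3_aa", "count"])
    rep = Repertoire.from_frame(sample_id, frame)
    rep.qc_applied = qc_applied
    return rep


def make_groups(rows) -> pd.DataFrame:
    """Build a groups table from (v_gene, cdr3_aa, degeneracy, total_count)."""
    df = pd.DataFrame(rows, columns=["v_gene", "cdr3_aa", "degeneracy", "total_count"])
    df["n_variants"] = df["degeneracy"]
    df["variants"] = [tuple(f"NT{i}_{j}" for j in range(d)) for i, d in enumerate(df["degeneracy"])]
    df.attrs["key_columns"] = ["v_gene", "cdr3_aa"]
    return df


def random_qc_cdr3_nt(rng: np.random.Generator, n_interior_codons: int) -> str:
    """A CDR3 nucleotide sequence whose translation passes QC (C...F)."""
    interior = "".join(rng.choice(NONSTOP_CODONS) for _ in range(n_interior_codons))
    return "TGT" + interior + "TTT"


def brute_force_degeneracy(records: pd.DataFrame) -> dict:
    """Nested-loop count of distinct nucleotide sequences per (v, aa) key."""
    out: dict = {}
    rows = list(records.itertuples(index=False))
    for row in rows:
        key = (row.v_gene, row.cdr3_aa)
        seen = set()
        for other in rows:
            if (other.v_gene, other.cdr3_aa) == key:
                seen.add(other.cdr3_nt)
        out[key] = len(seen)
    return out


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed table's (standard 1+1e-7
    tie tolerance).
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x: int) -> float:
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def binom_p_oracle(k: int, m: int, p0: float) -> float:
    """Exact two-sided binomial p by direct pmf summation."""

    def pmf(i: int) -> float:
        return comb(m, i) * p0**i * (1 - p0) ** (m - i)

    p_obs = pmf(k)
    return sum(pmf(i) for i in range(m + 1) if pmf(i) <= p_obs * (1 + 1e-7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
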