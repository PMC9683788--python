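# tcrconv

Analysis of **TCR convergence** in immune repertoires: T cell receptors that
are encoded by several distinct nucleotide rearrangements within one sample.
Because the genetic code is degenerate, independent V(D)J recombination events
can produce different CDR3 DNA sequences that translate to the identical
receptor protein. A receptor selected this way has, in effect, been "chosen"
repeatedly by antigen-driven selection, which makes convergence a useful
signal of antigen-specific T cell responses — and a candidate prognostic
biomarker for checkpoint-blockade immunotherapy.

The package is aimed at computational immunologists working with bulk TCRβ
repertoire tables (immunoSEQ-style or AIRR Rearrangement TSV) or 10x
single-cell V(D)J contig tables.

## The statistic

Within one sample, clonotypes are grouped by **(V gene, CDR3 amino-acid
sequence)** (for paired single-cell data, the β and α chains together). The
**degeneracy** of a group is the number of distinct CDR3 nucleotide sequences
encoding it:

- degeneracy *d* = 1 → non-convergent,
- *d* ≥ 2 → convergent; a sample's **convergence level** is its number of
  convergent groups.

Around this core the package provides:

- **Quality control** — CDR3s must be 8–23 residues, start with C, end with
  F, and use the 20 standard amino acids.
- **Degeneracy spectra and composition** — histogram of *d*, CDR3
  length/V-gene profiles, interior amino-acid composition per degeneracy
  class (first/last 3 residues excluded as V/J-templated), with exact
  two-sided binomial tests for per-residue usage shifts.
- **Publicity** — public TCRs are those present in ≥ threshold (default 5%,
  counted as `ceil(0.05 · N)` individuals) of a reference cohort; the overlap
  `|convergent ∩ public| / |convergent|` separates convergence from
  recombination-bias-driven sharing.
- **Enrichment** — Fisher's exact test of a TCR set against an
  antigen-specificity label set over the sample's unique TCRs, with a
  count-matched **expansion comparator**: the k most-expanded TCRs, k equal
  to the number of convergent TCRs, tested against the same labels.
- **Repertoire indices** — clonality = 1 − Pielou's evenness
  (`1 + Σ pᵢ log₂ pᵢ / log₂ n`) and diversity = n/N.
- **Prognosis** — median split of convergence levels into high/low groups;
  Kaplan–Meier/log-rank and multivariate Cox (clonality, diversity,
  treatment, sequencing depth as covariates) delegated to lifelines.
- **Synthetic repertoires** — a generator that plants an exact degeneracy
  spectrum by back-translating CDR3s through the genetic code, with
  power-law clone sizes, controllable label enrichment, and multi-individual
  sharing, plus a truth table for validation.

## Worked example

```python
from tcrconv import (SimulationConfig, simulate_repertoire, filter_repertoire,
                     compute_groups, convergence_summary, degeneracy_spectrum)

rep, truth = simulate_repertoire(SimulationConfig(seed=1, n_groups=10_000))
filtered, qc = filter_repertoire(rep)
groups = compute_groups(filtered)
print(convergence_summary(groups))
print(degeneracy_spectrum(groups).counts)
```

prints

```
{'n_groups': 10000, 'convergence_level': 540, 'convergent_clone_fraction': 0.054,
 'convergent_cell_fraction': 0.0627}
{1: 9460, 2: 490, 3: 39, 4: 11}
```

i.e. 5.4% of the 10,000 amino-acid-level TCRs are convergent (the generator's
default), 490 of them with two nucleotide variants, 39 with three, 11 with
four — the planted spectrum recovered exactly.

The same pipeline runs from the shell:

```bash
tcrconv simulate --seed 1 --n-groups 10000 --out simdir
tcrconv convergence --input simdir/sim.tsv --out-prefix results/conv
tcrconv stats --input simdir/sim.tsv --out results/stats.tsv
```

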