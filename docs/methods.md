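# Methods

## The convergence statistic

Within one sample, clonotypes — unique (V gene, CDR3 nucleotide sequence)
pairs — are partitioned by their amino-acid-level identity (V gene, CDR3
amino-acid sequence; for paired single-cell data the β and α chains
together). The degeneracy of a group is the number of distinct nucleotide
sequences it contains; groups with degeneracy ≥ 2 are convergent. Two
modelling commitments are built in:

- **Per-sample scope.** Degeneracy is never pooled across samples. Pooling
  would count the same receptor arising in two individuals as "convergent",
  which is publicity (recombination-bias-driven sharing), a different
  process. Publicity is computed by its own module, at the same
  (V gene, CDR3 aa) key, so the convergence–publicity overlap is
  well-defined.
- **Key without J.** The grouping key is V gene + CDR3 aa. The J segment is
  excluded by default (a `include_j` flag exists) because the receptor
  identity relevant to antigen binding is carried by the CDR3 and V-encoded
  loops. V genes are normalized by stripping allele suffixes (`*01` etc.);
  gene-level resolution is the default, family-level optional.

Descriptive statistics (degeneracy spectra, length and V-gene profiles,
amino-acid composition) weight each amino-acid-level group once —
unique-TCR weighting — rather than by read count, so heavily expanded
clones do not dominate sequence-feature summaries. Composition strips the
first and last three CDR3 residues, which are templated by the V/J germline
rather than junctional; with the QC minimum length of 8 the interior is
never empty. Composition is reported as pooled-residue proportions across
groups of one degeneracy class (an interpretation choice; per-group means
would weight short CDR3s more heavily).

## Quality control

A CDR3 amino-acid sequence passes iff: 8 ≤ length ≤ 23 (inclusive bounds),
first residue C, last residue F, all residues in the 20-letter alphabet.
The alphabet rule is a practical necessity — `*`, `X`, `_` mark
out-of-frame or ambiguous calls that would otherwise create spurious
"amino-acid" groups. Records failing several rules are attributed to the
first failing rule in the fixed order (alphabet, length, start, end), so
per-rule removal counts are deterministic and sum, with the retained
count, to the input count. Filtering is idempotent.

## Statistical procedures

- **Per-residue usage shifts** between degeneracy classes use the exact
  two-sided binomial test (scipy `binomtest`): observed count k of a
  residue among the m pooled interior residues of class d, against the
  class-1 proportion p₀; the two-sided p sums all outcome probabilities
  not exceeding the observed outcome's.
- **Enrichment** uses Fisher's exact test (scipy `fisher_exact`,
  two-sided) on the 2×2 table of set × label membership over the universe
  of the sample's unique amino-acid-level TCRs. The reported effect is the
  sample odds ratio (a·d)/(b·c) — not the conditional-MLE estimator some
  packages report — with Haldane–Anscombe +0.5 on all four cells iff any
  cell is zero (flagged in the result). The p-value is
  estimator-independent and carries the inference.
- **The matched-expansion comparator** selects the k groups with the
  highest total read counts, with k equal to the sample's number of
  convergent groups, so convergence and expansion are compared at equal
  set sizes. Ties at the k-th rank break deterministically: higher count
  first, then lexicographic (V gene, CDR3 aa).
- **Clonality** is 1 − Pielou's evenness, `1 + Σ pᵢ log₂ pᵢ / log₂ n`,
  over QC-passed nucleotide-level clonotype frequencies (the unit the
  sequencer reports). Zero frequencies are dropped (0·log 0 := 0, logged);
  n = 1 is signalled as undefined rather than defaulted, since log₂(1) = 0
  makes the formula singular and silent defaults would bias cohort
  summaries. The result is clipped to [0, 1] against floating-point drift.
  **Diversity** is n/N with N the total template count.
- **Publicity**: "present in at least a fraction t of the cohort" is
  implemented as ≥ ceil(t·N_individuals) individuals — the convention
  under which a 5% threshold on a 666-donor cohort requires 34 donors.
  Presence is binary; read depth plays no role.
- **Prognostic stratification**: samples are split at the cohort median
  convergence level (midpoint convention for even counts); above → high,
  below → low, exactly at the median → high with a mandatory tie report
  (the deterministic, visible alternative to dropping samples). A cohort
  with all levels identical refuses to stratify. Kaplan–Meier, log-rank
  and the multivariate Cox model (covariates: clonality, diversity,
  treatment, total detected clonotypes as sequencing depth) are delegated
  to lifelines and passed through unmodified; the bespoke content is the
  stratifying statistic and the table assembly, which carries exactly the
  named covariates.

## The synthetic-data generator

`simulate_repertoire` plants structure rather than sampling it:

1. For each group, a CDR3 is drawn — C + interior + F, length from a
   unimodal distribution on [8, 23] peaking at 14–15 residues, interior
   residues from a frequency vector mildly skewed toward S/G/Y/E (junctional
   CDR3s are serine/glycine-rich; fully configurable, no claim of
   quantitative realism).
2. The CDR3 is back-translated d times through a codon-usage model
   (uniform over synonymous codons by default), rejecting duplicate
   nucleotide sequences, which guarantees exactly d distinct variants.
   Short CDR3s rich in M/W can exhaust their encodings; after a bounded
   number of duplicate rejections (default 100) the CDR3 is redrawn.
   Group keys are kept unique, so the emitted file's realized spectrum
   equals the configured spectrum by construction, not approximately.
3. One clone size per group is drawn from a truncated discrete power law
   (exponent 2.5, minimum 1) and partitioned across the group's variants,
   each variant receiving at least one read. Drawing the total at the
   group level keeps expansion statistically independent of degeneracy —
   the property that makes the matched-expansion comparator a true
   neutral control in validation runs. (An earlier per-variant draw was
   discarded because it mechanically coupled group size to degeneracy.)
4. Specificity labels are Bernoulli: base probability q (default 0.2) for
   non-convergent groups and q′ = mq/(1−q+mq) for convergent ones, so the
   planted odds ratio is exactly the multiplier m. The default m = 9
   reflects the order of convergence–specificity enrichment seen in deep
   antigen-annotated repertoires; `expected_enrichment` returns the
   closed-form expected table.

The default degeneracy spectrum assigns 5.4% of groups to be convergent,
split 90.65% / 7.16% / rest across degeneracies 2 / 3 / 4 — roughly a
ten-fold decay per unit of degeneracy, the structure seen in deep healthy
repertoires.

`simulate_cohort` draws a master pool of keys and assigns each to each
individual i.i.d. with a sharing probability; carriers share the
amino-acid key but re-draw nucleotide variants independently. The truth
table records every group's sharing count, which the publicity derivation
must reproduce through the ceiling rule exactly.

`simulate_survival_cohort` draws tie-free convergence levels, assigns the
above-median group a hazard of `hazard_ratio × baseline` (default 0.3 ×
1/300 per day), exponential event times with administrative censoring at
1000 days, and independent noise covariates.

### What the generator does not emulate

Passing tests on these simulations shows the pipeline's bookkeeping and
inference are correct under the planted model; it does not certify
behaviour on real data, which additionally contains: sequencing errors
(which inflate apparent convergence and are explicitly out of scope here —
no error model is simulated), genuine correlation between clonal expansion
and antigen specificity (real expanded clones are antigen-enriched; the
generator's expansion is neutral by design, so the comparator's ~1.0 odds
ratio in validation is a floor, not a forecast), V(D)J generation-
probability structure (back-translation has no recombination model), and
batch effects across cohorts.

## Problem sizes and numerical choices

Validation runs use 10⁴-group repertoires (single-repertoire structure),
20–50 seeds × 5×10³ groups (enrichment recovery), 40-individual cohorts
(publicity; scaled down from reference-cohort sizes while keeping the 5%
rule exercised through the ceiling), and 60-sample survival cohorts —
sizes at which every planted quantity is recoverable and the full suite
runs in about a minute. Exact tests are delegated to scipy and validated
in-tree against independent enumeration oracles (math.comb hypergeometric
sums, direct pmf summation, nested-loop degeneracy counts). Report writers
sort canonically so identical inputs give byte-identical files; all
randomness flows from integer-seeded numpy generators with no dependence
on hash or iteration order.

## Known limitations

- Multi-β cells in single-cell data are excluded (not resolved); cells
  with several α chains keep the best-supported α. Both are choices where
  upstream conventions vary.
- The alphabet QC rule is an inferred necessity; upstream pipelines differ
  in how they mark ambiguous residues.
- The sample odds ratio with the +0.5 correction is biased for extreme
  tables; interpret flagged (zero-cell) results through their p-values.
- Publicity at desk scale is validated on synthetic cohorts; deriving a
  reference public set from real 666-donor data requires the external
  download and is out of scope.
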