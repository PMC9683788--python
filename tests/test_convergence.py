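"""Grouping, degeneracy and descriptive statistics of convergent TCRs."""

import numpy as np
import pandas as pd
import pytest

from tcrconv import (
    aa_composition,
    aa_enrichment_test,
    compute_groups,
    compute_paired_groups,
    convergence_summary,
    convergent_set,
    degeneracy_spectrum,
    length_and_vgene_profiles,
)
from tcrconv.convergence import exact_binomial_pvalue
from tcrconv.errors import ConfigurationError, UndefinedStatisticError
from tcrconv.repertoire import ClonotypeRecord, PairedCellRecord
from tcrconv.simulate import CODONS_BY_AA

from conftest import binom_p_oracle, brute_force_degeneracy, make_groups, make_repertoire, random_qc_cdr3_nt


class TestComputeGroups:
    def test_synonymous_variants_form_one_convergent_group(self):
        rep = make_repertoire(
            [
                ("TRBV19", "TGTGCCAGCAGCTTT", "CASSF", 3),
                ("TRBV19", "TGCGCCAGCAGCTTT", "CASSF", 1),
            ],
            qc_applied=True,
        )
        groups = compute_groups(rep)
        assert len(groups) == 1
        assert groups.loc[0, "degeneracy"] == 2
        assert groups.loc[0, "total_count"] == 4
        assert convergent_set(groups) == {("TRBV19", "CASSF")}

    def test_single_variant_is_not_convergent(self):
        rep = make_repertoire([("TRBV19", "TGTGCCAGCAGCTTT", "CASSF", 5)], qc_applied=True)
        groups = compute_groups(rep)
        assert groups.loc[0, "degeneracy"] == 1
        assert convergent_set(groups) == set()

    def test_v_gene_is_part_of_the_key(self):
        rep = make_repertoire(
            [
                ("TRBV19", "TGTGCCAGCAGCTTT", "CASSF", 1),
                ("TRBV20", "TGTGCCAGCAGCTTT", "CASSF", 1),
            ],
            qc_applied=True,
        )
        groups = compute_groups(rep)
        assert len(groups) == 2
        assert (groups["degeneracy"] == 1).all()

    def test_unfiltered_repertoire_refused(self):
        rep = make_repertoire([("TRBV19", "TGTGCCAGCAGCTTT", "CASSF", 1)], qc_applied=False)
        with pytest.raises(ConfigurationError):
            compute_groups(rep)

    def test_permutation_invariance(self, rng):
        from tcrconv import translate_cdr3

        rows = []
        for _ in range(60):
            nt = random_qc_cdr3_nt(rng, int(rng.integers(6, 10)))
            rows.append((f"TRBV{rng.integers(1, 5)}", nt, translate_cdr3(nt), 1))
        rep1 = make_repertoire(rows, qc_applied=True)
        rep2 = make_repertoire(rows[::-1], qc_applied=True)
        pd.testing.assert_frame_equal(compute_groups(rep1), compute_groups(rep2))

    def test_degeneracy_matches_brute_force_on_random_repertoires(self, rng):
        """Oracle equivalence on small random repertoires."""
        for _ in range(20):
            rows = []
            for _ in range(rng.integers(5, 100)):
                nt = random_qc_cdr3_nt(rng, int(rng.integers(6, 9)))
                from tcrconv import translate_cdr3

                rows.append((f"TRBV{rng.integers(1, 4)}", nt, translate_cdr3(nt), 1))
            rep = make_repertoire(rows, qc_applied=True)
            groups = compute_groups(rep)
            oracle = brute_force_degeneracy(rep.records)
            got = {
                (r.v_gene, r.cdr3_aa): r.degeneracy for r in groups.itertuples(index=False)
            }
            assert got == oracle

    def test_adding_synonymous_variant_increments_one_group_only(self):
        rows = [
            ("TRBV19", "TGTGCCAGCAGCTTT", "CASSF", 3),
            ("TRBV19", "TGCGCCAGCAGCTTT", "CASSF", 1),
            ("TRBV07", "TGTGCCGGGAGCTTC", "CAGSF", 2),
        ]
        before = compute_groups(make_repertoire(rows, qc_applied=True))
        # a third synonymous encoding of CASSF under TRBV19
        after = compute_groups(
            make_repertoire(rows + [("TRBV19", "TGTGCAAGCAGCTTT", "CASSF", 1)], qc_applied=True)
        )
        b = before.set_index(["v_gene", "cdr3_aa"])["degeneracy"]
        a = after.set_index(["v_gene", "cdr3_aa"])["degeneracy"]
        assert a[("TRBV19", "CASSF")] == b[("TRBV19", "CASSF")] + 1
        assert a[("TRBV07", "CAGSF")] == b[("TRBV07", "CAGSF")]


class TestSpectrumAndSummary:
    def test_spectrum_histogram_and_convergent_shares(self):
        groups = make_groups(
            [("V1", "CAAAAAAF", 1, 1), ("V1", "CAAAAACF", 1, 1),
             ("V1", "CAAAAADF", 2, 2), ("V1", "CAAAAAEF", 2, 2), ("V1", "CAAAAAGF", 3, 3)]
        )
        spec = degeneracy_spectrum(groups)
        assert spec.counts == {1: 2, 2: 2, 3: 1}
        assert spec.convergent_shares == {2: 2 / 3, 3: 1 / 3}

    def test_empty_input_gives_empty_spectrum(self):
        spec = degeneracy_spectrum(make_groups([]))
        assert spec.counts == {}
        assert spec.n_groups == 0

    def test_conservation_identities(self, rng):
        """Sum over d of spectrum[d] is the group count; sum of d*spectrum[d]
        is the nucleotide-level clonotype count."""
        from tcrconv import translate_cdr3

        rows = []
        for _ in range(80):
            nt = random_qc_cdr3_nt(rng, int(rng.integers(6, 9)))
            rows.append((f"TRBV{rng.integers(1, 4)}", nt, translate_cdr3(nt), 1))
        rep = make_repertoire(rows, qc_applied=True)
        groups = compute_groups(rep)
        spec = degeneracy_spectrum(groups)
        assert spec.n_groups == len(groups)
        assert spec.n_clonotypes == rep.n_clonotypes

    def test_clone_fraction(self):
        groups = make_groups(
            [("V1", f"CAAAAA{aa}F", d, 1) for aa, d in zip("ACDEG", [1, 1, 1, 2, 2])]
        )
        summary = convergence_summary(groups)
        assert summary["convergence_level"] == 2
        assert summary["convergent_clone_fraction"] == pytest.approx(0.4)


class TestPairedMode:
    def _cell(self, bc, bv, baa, bnt, av=None, aaa=None, ant=None):
        beta = ClonotypeRecord("s", bnt, baa, bv)
        alpha = ClonotypeRecord("s", ant, aaa, av) if av else None
        return PairedCellRecord(bc, beta, alpha)

    def test_degeneracy_counts_distinct_chain_pairs(self):
        cells = [
            self._cell("b1", "TRBV19", "CASSIRSSYEQYF", "NT1", "TRAV1", "CAVSDGGYQKVTF", "AT1"),
            self._cell("b2", "TRBV19", "CASSIRSSYEQYF", "NT2", "TRAV1", "CAVSDGGYQKVTF", "AT1"),
            self._cell("b3", "TRBV19", "CASSIRSSYEQYF", "NT1", "TRAV1", "CAVSDGGYQKVTF", "AT1"),
        ]
        groups = compute_paired_groups(cells)
        assert len(groups) == 1
        assert groups.loc[0, "degeneracy"] == 2  # (NT1,AT1) and (NT2,AT1)
        assert groups.loc[0, "total_count"] == 3  # cells

    def test_different_alpha_separates_groups(self):
        cells = [
            self._cell("b1", "TRBV19", "CASSIRSSYEQYF", "NT1", "TRAV1", "CAVSDGGYQKVTF", "AT1"),
            self._cell("b2", "TRBV19", "CASSIRSSYEQYF", "NT1", "TRAV2", "CAVSDGGYQKVTF", "AT2"),
        ]
        assert len(compute_paired_groups(cells)) == 2

    def test_qc_failing_beta_dropped(self):
        cells = [self._cell("b1", "TRBV19", "CASS", "NT1")]  # too short
        assert len(compute_paired_groups(cells)) == 0


class TestProfiles:
    def test_single_group_length_profile(self):
        prof = length_and_vgene_profiles(make_groups([("TRBV19-1", "CASSIRSSYEQYF", 1, 1)]))
        assert prof["length"].loc[13, "n_groups"] == 1

    def test_family_counts_pool_genes(self):
        prof = length_and_vgene_profiles(
            make_groups([("TRBV6-2", "CAAAAAAF", 1, 1), ("TRBV6-3", "CAAAAACF", 2, 1)])
        )
        assert prof["v_family"].loc["TRBV6", "n_groups"] == 2
        assert prof["v_family"].loc["TRBV6", "n_convergent"] == 1

    def test_mean_degeneracy_per_length_matches_hand_computation(self):
        groups = make_groups(
            [
                ("V1", "CAAAAAAF", 1, 1),   # len 8
                ("V1", "CAAAAACF", 3, 1),   # len 8
                ("V1", "CAAAAAADF", 2, 1),  # len 9
                ("V2", "CAAAAAAEF", 4, 1),  # len 9
                ("V2", "CAAAAAAGF", 3, 1),  # len 9
            ]
        )
        prof = length_and_vgene_profiles(groups)["length"]
        assert prof.loc[8, "mean_degeneracy"] == pytest.approx(2.0)
        assert prof.loc[9, "mean_degeneracy"] == pytest.approx(3.0)


class TestAAComposition:
    def test_interior_letter_tally(self):
        comp = aa_composition(make_groups([("V1", "CASSIRSSYEQYF", 1, 1)]), degeneracy=1)
        # interior is SIRSSYE
        props = comp.proportions
        assert props["S"] == pytest.approx(3 / 7)
        for aa in "IRYE":
            assert props[aa] == pytest.approx(1 / 7)
        assert comp.total == 7

    def test_proportions_sum_to_one(self):
        comp = aa_composition(
            make_groups([("V1", "CASSIRSSYEQYF", 2, 1), ("V1", "CAWWWWWWF", 2, 1)]), degeneracy=2
        )
        assert comp.proportions.sum() == pytest.approx(1.0)

    def test_pooled_counts_match_brute_force_tally(self):
        seqs = ["CASSIRSSYEQYF", "CAWSGELFF", "CASSPGQGAYEQYF"]
        groups = make_groups([("V1", s, 2, 1) for s in seqs])
        comp = aa_composition(groups, degeneracy=2)
        pooled = "".join(s[3:-3] for s in seqs)
        for aa in set(pooled):
            assert comp.counts[aa] == pooled.count(aa)
        assert comp.total == len(pooled)

    def test_groups_counted_once_not_read_weighted(self):
        groups = make_groups([("V1", "CASSIRSSYEQYF", 1, 500), ("V1", "CAYYYYYYF", 1, 1)])
        comp = aa_composition(groups, degeneracy=1)
        # 500 reads do not inflate the first group's contribution
        assert comp.counts["Y"] == 1 + 3  # one Y in SIRSSYE + YYY from the second group


class TestBinomialEnrichment:
    @pytest.mark.parametrize(
        "k,m,p0,expected",
        [(5, 10, 0.5, 1.0), (10, 10, 0.5, 2 / 1024), (0, 1, 0.5, 1.0)],
    )
    def test_known_values(self, k, m, p0, expected):
        assert exact_binomial_pvalue(k, m, p0) == pytest.approx(expected, rel=1e-12)

    def test_matches_pmf_summation_oracle(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 60))
            k = int(rng.integers(0, m + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            assert exact_binomial_pvalue(k, m, p0) == pytest.approx(
                binom_p_oracle(k, m, p0), rel=1e-9
            )

    def test_composition_interface(self):
        base = aa_composition(
            make_groups([("V1", "CASSSSSSYF", 1, 1), ("V1", "CAYYYYYYF", 1, 1)]), 1
        )
        conv = aa_composition(make_groups([("V1", "CASSSSSSYF", 2, 1)]), 2)
        p = aa_enrichment_test(conv, base, "S")
        assert 0.0 <= p <= 1.0

    def test_empty_class_signalled(self):
        base = aa_composition(make_groups([("V1", "CASSSSSSYF", 1, 1)]), 1)
        empty = aa_composition(make_groups([("V1", "CASSSSSSYF", 1, 1)]), 5)
        with pytest.raises(UndefinedStatisticError):
            aa_enrichment_test(empty, base, "S")
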