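"""Mendelian selfing expectations, deviation tests, family summaries and the
model/results interface, benchmarked against the published six-family cacao
dataset bundled in ``selfpath.datasets``."""

import numpy as np
import pandas as pd
import pytest

from selfpath import (
    GenotypeCounts,
    SelfingFamilyModel,
    expected_next_counts,
    family_summary,
    load_cacao_counts,
    mendelian_deviation_test,
    propagate_homozygosity,
    rank_and_select,
    standardized_homozygosity,
    surrogate_parent_counts,
)
from selfpath.simulate import SimulationConfig, simulate_selfing_study

TSH1188 = GenotypeCounts(812, 1770, 798)
TSH1188_S1_2 = GenotypeCounts(924, 1542, 914)


class TestExpectedNextCounts:
    def test_quarter_gain_half_loss(self):
        e = expected_next_counts(TSH1188)
        assert (e.e_aa, e.e_ab, e.e_bb) == (1254.5, 885.0, 1240.5)

    def test_fully_homozygous_parent_is_fixed_point(self):
        e = expected_next_counts(GenotypeCounts(1000, 0, 0))
        assert (e.e_aa, e.e_ab, e.e_bb) == (1000.0, 0.0, 0.0)

    def test_heterozygosity_halves_geometrically(self):
        c = GenotypeCounts(0, 4096, 0)
        for g in range(1, 6):
            e = expected_next_counts(c)
            assert e.e_ab == 4096 / 2**g
            c = GenotypeCounts(e.e_aa, e.e_ab, e.e_bb)

    def test_total_conserved(self):
        for counts in (TSH1188, GenotypeCounts(3, 5, 11), GenotypeCounts(0, 7, 0)):
            assert expected_next_counts(counts).total == pytest.approx(counts.total)

    def test_rescaling_changes_scale_not_proportions(self):
        e = expected_next_counts(TSH1188, rescale_to=1690)
        assert e.total == pytest.approx(1690)
        assert e.hom_fraction == pytest.approx(
            expected_next_counts(TSH1188).hom_fraction
        )


class TestPropagateHomozygosity:
    def test_one_generation_reference_values(self):
        assert round(propagate_homozygosity(1838 / 3380, 1), 3) == 0.772
        assert round(propagate_homozygosity(2506 / 3380, 1), 3) == 0.871
        assert round(propagate_homozygosity(1610 / 3380, 1), 3) == 0.738

    def test_fixed_points_and_limit(self):
        assert propagate_homozygosity(1.0, 5) == 1.0
        assert propagate_homozygosity(0.3, 0) == 0.3
        assert propagate_homozygosity(0.3, 40) == pytest.approx(1.0)

    def test_monotone_in_generations(self):
        hs = [propagate_homozygosity(0.476, g) for g in range(6)]
        assert hs == sorted(hs)

    def test_agrees_with_count_propagation(self):
        # closed form == homozygous fraction of the expected counts
        e = expected_next_counts(TSH1188)
        h0 = (TSH1188.n_aa + TSH1188.n_bb) / TSH1188.total
        assert e.hom_fraction == pytest.approx(propagate_homozygosity(h0, 1))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            propagate_homozygosity(1.2, 1)


class TestDeviationTest:
    def test_s1_against_founder(self):
        t = mendelian_deviation_test(TSH1188_S1_2, TSH1188)
        assert round(t.chi2, 2) == 660.74
        assert t.significant and t.direction == "below"

    def test_s2_against_s1(self):
        t = mendelian_deviation_test(GenotypeCounts(1193, 1044, 1141), TSH1188_S1_2)
        assert round(t.chi2, 2) == 126.36

    def test_exact_expectation_gives_zero(self):
        e = expected_next_counts(TSH1188)
        t = mendelian_deviation_test(
            GenotypeCounts(e.e_aa, e.e_ab, e.e_bb), TSH1188
        )
        assert t.chi2 == pytest.approx(0.0, abs=1e-12)
        assert not t.significant

    def test_rescaled_variant_differs_slightly(self):
        obs = GenotypeCounts(1193, 1044, 1141)  # total 3378 != parent's 3380
        plain = mendelian_deviation_test(obs, TSH1188_S1_2)
        scaled = mendelian_deviation_test(obs, TSH1188_S1_2, rescale=True)
        assert round(plain.chi2, 2) == 126.36
        assert round(scaled.chi2, 2) == 126.44

    def test_zero_expected_class_flags_infinite_deviation(self):
        t = mendelian_deviation_test(
            GenotypeCounts(5, 1, 4), GenotypeCounts(10, 0, 0)
        )
        assert t.infinite_deviation and np.isinf(t.chi2) and t.p == 0.0

    def test_null_rejection_rate_matches_alpha(self, rng):
        # offspring drawn multinomially from the Mendelian expectation
        parent = TSH1188_S1_2
        e = expected_next_counts(parent)
        probs = e.as_array() / e.total
        rejections = 0
        n_reps = 2000
        draws = rng.multinomial(int(parent.total), probs, size=n_reps)
        for d in draws:
            t = mendelian_deviation_test(GenotypeCounts(*d), parent)
            rejections += t.significant
        assert rejections / n_reps == pytest.approx(0.05, abs=0.015)


class TestSurrogateParent:
    def test_mean_of_the_two_siblings(self):
        s = surrogate_parent_counts(
            [GenotypeCounts(924, 1542, 914), GenotypeCounts(909, 1536, 934)]
        )
        assert (s.n_aa, s.n_ab, s.n_bb) == (916.5, 1539.0, 924.0)

    def test_single_sibling_and_idempotent_mean(self):
        c = GenotypeCounts(10, 20, 30)
        assert surrogate_parent_counts([c]) == c
        assert surrogate_parent_counts([c, c, c]) == c

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            surrogate_parent_counts([])


class TestStandardizedHomozygosity:
    def test_zero_mean_unit_sd(self, rng):
        z = standardized_homozygosity(rng.random(9))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_degenerate_family(self):
        with pytest.raises(ValueError, match="sigma = 0"):
            standardized_homozygosity([0.7, 0.7, 0.7])
        with pytest.raises(ValueError, match="at least 2"):
            standardized_homozygosity([0.7])


class TestFamilySummary:
    def test_exactly_at_expectation(self):
        parent = GenotypeCounts(1000, 800, 1000)
        e = expected_next_counts(parent)
        kid = GenotypeCounts(e.e_aa, e.e_ab, e.e_bb)
        fs = family_summary([kid, kid], parent)
        assert fs.rmsd == pytest.approx(0.0, abs=1e-12)
        assert fs.t_stat == 0.0 and fs.t_p == 1.0

    def test_fewer_than_two_offspring_is_error(self):
        with pytest.raises(ValueError):
            family_summary([TSH1188_S1_2], TSH1188)


class TestPublishedTableRegression:
    """The six cacao families: every printed per-individual and per-family
    value must be reproduced from the raw genotypic counts."""

    def test_founder_homozygosities(self, cacao_offspring):
        hom = cacao_offspring["obs_hom"].round(3)
        assert hom["TSH-1188"] == 0.476
        assert hom["CCN-51"] == 0.454
        assert hom["PS-13.19"] == 0.491
        assert hom["SIAL-169"] == 0.969

    def test_expected_homozygosities(self, cacao_offspring):
        exp = cacao_offspring["exp_hom"].round(3)
        assert exp["TSH-1188_S1_2"] == 0.738
        assert exp["TSH-1188_S2_2_4"] == 0.772
        assert exp["TSH-1188_S2_1_3"] == 0.773
        assert exp["PS-13.19_S1_9"] == 0.745
        assert exp["CCN-51_S2_1_7"] == 0.871
        assert exp["SIAL-169_S1_3"] == 0.984

    @pytest.mark.parametrize(
        "individual,chi2",
        [
            ("TSH-1188_S1_2", 660.74),
            ("TSH-1188_S1_3", 649.75),
            ("TSH-1188_S2_2_2", 126.36),
            ("TSH-1188_S2_2_4", 157.30),
            ("TSH-1188_S2_1_1", 21.38),  # family C, designated-sibling parent
            ("TSH-1188_S2_1_3", 42.30),
            ("PS-13.19_S1_9", 343.79),
            ("CCN-51_S1_1", 3.90),
            ("SIAL-169_S1_1", 6.93),
        ],
    )
    def test_chi_square_values(self, cacao_offspring, individual, chi2):
        assert round(cacao_offspring.loc[individual, "chi2"], 2) == chi2

    @pytest.mark.parametrize(
        "individual,z",
        [
            ("TSH-1188_S2_2_2", -1.879),
            ("TSH-1188_S2_2_4", 1.523),
            ("TSH-1188_S2_3_5", 0.529),
            ("PS-13.19_S1_1", -1.622),
            ("CCN-51_S2_1_7", 1.101),
            ("SIAL-169_S1_1", -1.892),
        ],
    )
    def test_standardized_homozygosities(self, cacao_offspring, individual, z):
        assert round(cacao_offspring.loc[individual, "z"], 3) == z

    def test_family_table(self, cacao_fit):
        fam = cacao_fit.families
        assert list(fam.index) == list("ABCDEF")
        assert fam["observed_mean_hom"].round(3).tolist() == [
            0.786, 0.753, 0.789, 0.715, 0.868, 0.985,
        ]
        assert fam["expected_mean_hom"].round(3).tolist() == [
            0.772, 0.773, 0.773, 0.745, 0.871, 0.984,
        ]
        assert fam["sd"].round(3).tolist() == [
            0.050, 0.046, 0.030, 0.055, 0.010, 0.003,
        ]
        assert fam["rmsd"].round(3).tolist() == [
            0.049, 0.046, 0.032, 0.060, 0.010, 0.003,
        ]
        assert fam["min_hom"].round(3).tolist() == [
            0.691, 0.704, 0.740, 0.625, 0.849, 0.979,
        ]
        assert fam["max_hom"].round(3).tolist() == [
            0.862, 0.814, 0.818, 0.791, 0.879, 0.988,
        ]

    def test_family_t_test_p_values(self, cacao_fit):
        # the family-level deviation test: two-sided p of the one-sample t on
        # (observed - expected) homozygous counts
        assert cacao_fit.families["t_p"].round(3).tolist() == [
            0.489, 0.335, 0.373, 0.027, 0.342, 0.572,
        ]

    def test_sibling_mean_surrogate_is_the_default(self):
        fit = SelfingFamilyModel.from_counts_table(load_cacao_counts()).fit()
        off = fit.offspring.set_index("individual")
        assert off.loc["TSH-1188_S2_1_1", "surrogate_parent"]
        # sib-mean parent shifts the family-C chi2 away from the printed value
        assert round(off.loc["TSH-1188_S2_1_3", "chi2"], 2) == pytest.approx(42.96, abs=0.01)
        assert fit.families.loc["C", "expected_mean_hom"] == pytest.approx(0.772, abs=5e-4)

    def test_selection_picks_top_z_per_family(self, cacao_fit):
        top = cacao_fit.select(k=1).set_index("family")
        assert top.loc["A", "individual"] == "TSH-1188_S2_2_4"
        assert top.loc["E", "individual"] == "CCN-51_S2_1_7"
        assert top.loc["D", "individual"] == "PS-13.19_S1_9"


class TestRankAndSelect:
    def _table(self):
        return pd.DataFrame(
            {
                "family": ["X"] * 3,
                "individual": ["b", "a", "c"],
                "z": [1.0, 1.0, -0.5],
            }
        )

    def test_tie_broken_lexicographically(self):
        sel = rank_and_select(self._table(), k=1)
        assert sel["individual"].tolist() == ["a"]

    def test_k_equals_family_size_orders_by_z(self):
        sel = rank_and_select(self._table(), k=3)
        assert sel["individual"].tolist() == ["a", "b", "c"]

    def test_z_cutoff(self):
        sel = rank_and_select(self._table(), z_cutoff=0.0)
        assert sel["individual"].tolist() == ["a", "b"]

    def test_k_larger_than_family_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            rank_and_select(self._table(), k=4)

    def test_exactly_one_mode(self):
        with pytest.raises(ValueError):
            rank_and_select(self._table())


class TestModelFromMatrix:
    def test_matrix_and_counts_routes_agree(self):
        study = simulate_selfing_study(
            SimulationConfig(n_markers=400, n_generations=2, family_size=5, seed=12),
            n_families=2,
        )
        model = SelfingFamilyModel.from_matrix(study.matrix, study.pedigree)
        fit = model.fit()
        # rebuild via the counts-only route and compare the fitted tables
        rows = []
        for rec in study.pedigree:
            from selfpath import count_genotypes

            c = count_genotypes(study.matrix, rec.individual_id)
            rows.append(
                (rec.family_id, rec.generation, rec.individual_id,
                 rec.parent_id, c.n_aa, c.n_ab, c.n_bb)
            )
        table = pd.DataFrame(
            rows, columns=["family", "generation", "individual", "parent", "n_aa", "n_ab", "n_bb"]
        )
        fit2 = SelfingFamilyModel.from_counts_table(table).fit()
        pd.testing.assert_frame_equal(
            fit.offspring.reset_index(drop=True), fit2.offspring.reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(fit.families, fit2.families)

    def test_summary_mentions_families_and_alpha(self, cacao_fit):
        text = cacao_fit.summary()
        assert "alpha = 0.05" in text
        assert "TSH-1188_S2_2_4" in text and "Family summaries" in text
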