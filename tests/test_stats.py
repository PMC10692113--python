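"""Repeated-measures battery: Wilcoxon, rmANOVA/GG, Friedman, FDR, bootstrap."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from babytrf.stats import (
    EXACT_WILCOXON_MAX_N,
    assumption_screen,
    bootstrap_topography_similarity,
    fdr_bh,
    friedman_kendall,
    greenhouse_geisser_epsilon,
    mauchly_test,
    rm_anova_oneway,
    wilcoxon_signed_rank,
)


class TestWilcoxonExact:
    def test_three_positive_values_give_quarter(self):
        # all signs positive, n=3: P(T+ >= 6) = 1/8, two-tailed p = 1/4
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert res.p == pytest.approx(0.25)
        assert res.statistic == pytest.approx(6.0)
        assert res.n == 3

    def test_symmetric_differences_give_p_one(self):
        res = wilcoxon_signed_rank(np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]))
        assert res.p == pytest.approx(1.0)

    def test_matches_itertools_enumeration_oracle(self, rng):
        d = rng.standard_normal(10)
        res = wilcoxon_signed_rank(d)
        ranks = sstats.rankdata(np.abs(d))
        t_obs = ranks[d > 0].sum()
        t_all = np.array([np.dot(s, ranks)
                          for s in itertools.product((0, 1), repeat=10)])
        p_low = np.mean(t_all <= t_obs + 1e-9)
        p_high = np.mean(t_all >= t_obs - 1e-9)
        assert res.p == pytest.approx(min(1.0, 2 * min(p_low, p_high)))

    def test_matches_scipy_exact_mode(self, rng):
        d = rng.standard_normal(12)
        res = wilcoxon_signed_rank(d)
        ref = sstats.wilcoxon(d, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue)

    def test_paired_equals_one_sample_on_differences(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        assert wilcoxon_signed_rank(x, y=y).p == \
            pytest.approx(wilcoxon_signed_rank(x - y).p)

    def test_zeros_dropped_before_ranking(self):
        res = wilcoxon_signed_rank(np.array([0.0, 0.0, 1.0, 2.0, 3.0]))
        assert res.n == 3
        assert res.p == pytest.approx(0.25)

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.standard_normal(EXACT_WILCOXON_MAX_N + 10) + 0.4
        res = wilcoxon_signed_rank(d)
        ref = sstats.wilcoxon(d, correction=True, alternative="two-sided",
                              method="approx")
        assert res.p == pytest.approx(ref.pvalue)

    def test_all_zero_differences_raise(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(6))

    def test_too_few_nonzero_raise(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.array([0.0, 0.0, 0.0, 1.0, 2.0]))


class TestRmAnova:
    def test_no_condition_effect_gives_zero_f(self, rng):
        subj = rng.standard_normal(10)
        data = np.tile(subj[:, None], (1, 3))
        data += rng.standard_normal((10, 3)) * 0.0
        # perfectly identical conditions: SS_cond = 0
        res = rm_anova_oneway(np.tile(subj[:, None], (1, 3)))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_conditions_equal_paired_t_squared(self, rng):
        data = rng.standard_normal((12, 2))
        data[:, 1] += 0.5
        res = rm_anova_oneway(data)
        t = sstats.ttest_rel(data[:, 0], data[:, 1])
        assert res.statistic == pytest.approx(t.statistic ** 2)
        assert res.p == pytest.approx(t.pvalue)
        assert res.df == (1.0, 11.0)
        assert res.correction == "none"

    def test_sum_of_squares_decomposition(self, rng):
        data = rng.standard_normal((8, 4))
        n, k = data.shape
        grand = data.mean()
        ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_tot = ((data - grand) ** 2).sum()
        ss_err = ss_tot - ss_subj - ss_cond
        F = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        res = rm_anova_oneway(data, alpha_sphericity=0.0)  # force no GG
        assert res.statistic == pytest.approx(F)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        data = rng.standard_normal((15, 3))
        data[:, 2] += 0.6
        n, k = data.shape
        long = pd.DataFrame({
            "y": data.ravel(),
            "subj": np.repeat(np.arange(n), k),
            "cond": np.tile(np.arange(k), n),
        })
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                          correction=True)
        res = rm_anova_oneway(data)
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        p_ref = float(ref["p_GG_corr"][0]) if res.correction != "none" \
            else float(ref["p_unc"][0])
        assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(2024)
        ps = np.array([rm_anova_oneway(rng.standard_normal((10, 3))).p
                       for _ in range(500)])
        ks = sstats.kstest(ps, "uniform").statistic
        assert ks < 0.08

    def test_nan_rejected(self):
        data = np.ones((5, 3))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_oneway(data)


class TestSphericity:
    def test_compound_symmetric_epsilon_is_one(self, rng):
        # compound symmetry -> sphericity holds -> eps = 1
        subj = rng.standard_normal(200)[:, None]
        data = subj + rng.standard_normal((200, 4)) * 0.5
        eps = greenhouse_geisser_epsilon(data)
        assert eps > 0.97

    def test_epsilon_lower_bound_for_rank_one_structure(self, rng):
        # one dominant contrast direction drives eps toward 1/(k-1)
        k = 4
        u = np.array([1.5, -0.5, -0.5, -0.5])
        data = rng.standard_normal(60)[:, None] * u \
            + 1e-4 * rng.standard_normal((60, k))
        eps = greenhouse_geisser_epsilon(data)
        assert eps < 1.0 / (k - 1) + 0.02

    def test_epsilon_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        data = rng.standard_normal((20, 4))
        data[:, 0] *= 3.0
        ref = pg.epsilon(pd.DataFrame(data), correction="gg")
        assert greenhouse_geisser_epsilon(data) == pytest.approx(
            float(ref), rel=1e-9)

    def test_mauchly_two_conditions_trivial(self, rng):
        W, chi2, df, p = mauchly_test(rng.standard_normal((10, 2)))
        assert (W, chi2, df, p) == (1.0, 0.0, 0, 1.0)

    def test_mauchly_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        data = rng.standard_normal((25, 4))
        data[:, 1] *= 2.5
        W, chi2, df, p = mauchly_test(data)
        spher, W_ref, chi2_ref, df_ref, p_ref = pg.sphericity(pd.DataFrame(data))
        assert W == pytest.approx(float(W_ref), rel=1e-9)
        assert chi2 == pytest.approx(float(chi2_ref), rel=1e-9)
        assert df == int(df_ref)
        # pingouin adds a second-order term to the chi-square approximation;
        # the first-order p agrees to within a few percent
        assert p == pytest.approx(float(p_ref), rel=0.05)

    def test_mauchly_rejects_strong_heteroscedasticity(self, rng):
        data = rng.standard_normal((40, 4))
        data[:, 0] *= 10.0
        assert mauchly_test(data)[3] < 0.01


class TestFriedman:
    def test_perfectly_concordant_rankings_give_w_one(self):
        data = np.tile([1.0, 2.0, 3.0, 4.0], (6, 1))
        data += np.arange(6)[:, None]  # subject offsets keep concordance
        res = friedman_kendall(data)
        assert res.effect_size == pytest.approx(1.0)
        assert res.effect_name == "kendall_w"

    def test_kendall_identity_w_equals_chi2_over_nk1(self, rng):
        data = rng.standard_normal((9, 4))
        res = friedman_kendall(data)
        assert res.effect_size == pytest.approx(res.statistic / (9 * 3))

    def test_untied_formula_oracle(self, rng):
        # classic formula chi2 = 12/(n k (k+1)) * sum Rj^2 - 3 n (k+1),
        # valid when there are no ties within any subject
        data = rng.standard_normal((4, 3))
        n, k = data.shape
        ranks = np.vstack([sstats.rankdata(row) for row in data])
        Rj = ranks.sum(axis=0)
        chi2 = 12.0 / (n * k * (k + 1)) * (Rj ** 2).sum() - 3 * n * (k + 1)
        res = friedman_kendall(data)
        assert res.statistic == pytest.approx(chi2)

    def test_constant_rows_raise(self):
        with pytest.raises(ValueError):
            friedman_kendall(np.ones((5, 3)))


class TestFdr:
    def test_hand_worked_example(self):
        # sorted p * m / rank, then cummin from the right:
        # [.01*4/1, .04*4/2, .03*4/3 -> reordered] computed by hand
        p = np.array([0.01, 0.04, 0.03, 0.9])
        out = fdr_bh(p)
        assert out == pytest.approx([0.04, 0.053333333333, 0.053333333333, 0.9])

    def test_output_capped_at_one(self, rng):
        p = rng.uniform(size=12)
        out = fdr_bh(p)
        assert np.all(out <= 1.0)
        assert np.allclose(fdr_bh(np.ones(5)), 1.0)

    def test_order_preserving(self, rng):
        p = np.sort(rng.uniform(size=10))
        out = fdr_bh(p)
        assert np.all(np.diff(out) >= -1e-12)

    def test_never_smaller_than_raw(self, rng):
        p = rng.uniform(size=20)
        assert np.all(fdr_bh(p) >= p - 1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([]))
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.2, 1.5]))
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.2, np.nan]))


class TestAssumptionScreen:
    def test_normal_data_mostly_keeps_anova(self):
        picks = []
        for s in range(100):
            data = np.random.default_rng(s).standard_normal((12, 3))
            picks.append(assumption_screen(data))
        frac_anova = np.mean([p.startswith("rmANOVA") for p in picks])
        assert frac_anova >= 0.80  # a few false Shapiro rejections expected

    def test_heavy_skew_routes_to_friedman(self):
        picks = []
        for s in range(60):
            data = np.random.default_rng(1000 + s).standard_normal((20, 3)) ** 3
            picks.append(assumption_screen(data))
        assert np.mean([p == "Friedman" for p in picks]) > 0.5

    def test_sphericity_violation_routes_to_gg(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((60, 4))
        data[:, 0] *= 8.0
        if assumption_screen(data) != "Friedman":
            assert assumption_screen(data) == "rmANOVA+GG"

    def test_tiny_table_raises(self):
        with pytest.raises(ValueError):
            assumption_screen(np.ones((2, 3)))


class TestBootstrapTopography:
    def test_identical_maps_give_one(self, rng):
        ref = rng.standard_normal(32)
        topo = np.tile(ref, (20, 1))
        mean_r, draws = bootstrap_topography_similarity(topo, ref, seed=3)
        assert mean_r == pytest.approx(1.0)
        assert np.allclose(draws, 1.0)

    def test_seed_determinism(self, rng):
        topo = rng.standard_normal((30, 16))
        ref = rng.standard_normal(16)
        a = bootstrap_topography_similarity(topo, ref, seed=42)
        b = bootstrap_topography_similarity(topo, ref, seed=42)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_draw_count_contract(self, rng):
        topo = rng.standard_normal((10, 8))
        _, draws = bootstrap_topography_similarity(topo, rng.standard_normal(8),
                                                   iterations=37, seed=0)
        assert draws.shape == (37,)

    def test_planted_similarity_ordering(self, rng):
        # cohorts built around the reference map should outrank noise cohorts
        ref = rng.standard_normal(24)
        wins = 0
        n_rep = 40
        for i in range(n_rep):
            r = np.random.default_rng(500 + i)
            aligned = ref + 0.8 * r.standard_normal((15, 24))
            noise = r.standard_normal((15, 24))
            ra, _ = bootstrap_topography_similarity(aligned, ref, group_size=8,
                                                    iterations=30, seed=i)
            rn, _ = bootstrap_topography_similarity(noise, ref, group_size=8,
                                                    iterations=30, seed=i)
            wins += ra > rn
        assert wins >= 0.95 * n_rep

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            bootstrap_topography_similarity(rng.standard_normal((5, 8)),
                                            rng.standard_normal(9))
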