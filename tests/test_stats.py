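"""Statistical battery: block rank tests, post hocs, KDE, trend fits."""

import numpy as np
import pytest
import scipy.stats as sps

from twitchscope.stats import (
    BlockDesignData,
    DesignError,
    ExpTrendModel,
    diffusion_kde,
    dunn_posthoc,
    f_test_model_equivalence,
    fit_exp_trend,
    gore_test,
    ks_two_sample,
    pearson_r,
    rank_sum_test,
    skillings_mack_test,
)


def long_format(table: np.ndarray, replicates: int = 1, missing=()):
    """Blocks x treatments (x replicates) array -> long-format triples."""
    blocks, treats, values = [], [], []
    n_b, n_t = table.shape[:2]
    for i in range(n_b):
        for j in range(n_t):
            if (i, j) in missing:
                continue
            cell = np.atleast_1d(table[i, j])
            for v in cell:
                blocks.append(i)
                treats.append(j)
                values.append(float(v))
    return np.array(blocks), np.array(treats), np.array(values)


class TestGore:
    def test_all_equal_observations_give_null(self):
        table = np.ones((4, 3, 2))
        d = BlockDesignData(*long_format(table, replicates=2))
        res = gore_test(d)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_shift_detected(self):
        rng = np.random.default_rng(0)
        table = rng.normal(0, 1, (5, 3, 3))
        table[:, 2, :] += 10.0
        d = BlockDesignData(*long_format(table))
        assert gore_test(d).p_value < 0.001

    def test_reduces_to_friedman_without_replication(self):
        rng = np.random.default_rng(1)
        table = rng.normal(0, 1, (8, 4))
        d = BlockDesignData(*long_format(table))
        res = gore_test(d)
        ref = sps.friedmanchisquare(*[table[:, j] for j in range(4)])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)

    def test_equal_replication_closed_form(self):
        # closed form for c replicates per cell, no ties:
        # 12 (k-1) sum (T_j - nc(N+1)/2)^2 / (k n c (N+1)(N-c)), N = kc
        rng = np.random.default_rng(2)
        n_b, k, c = 5, 3, 2
        table = rng.normal(0, 1, (n_b, k, c))
        d = BlockDesignData(*long_format(table))
        res = gore_test(d)
        N = k * c
        T = np.zeros(k)
        for i in range(n_b):
            ranks = sps.rankdata(table[i].ravel()).reshape(k, c)
            T += ranks.sum(axis=1)
        num = 12 * (k - 1) * np.sum((T - n_b * c * (N + 1) / 2) ** 2)
        den = k * n_b * c * (N + 1) * (N - c)
        assert res.statistic == pytest.approx(num / den, abs=1e-9)

    def test_asymptotic_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(3)
        table = rng.normal(0, 1, (3, 3, 2))
        table[:, 1, :] += 1.0
        d = BlockDesignData(*long_format(table))
        p_asym = gore_test(d).p_value
        p_perm = gore_test(d, method="permutation", n_permutations=20000,
                           seed=4).p_value
        assert abs(p_asym - p_perm) <= 0.05

    def test_design_error_on_single_treatment_blocks(self):
        blocks = np.array([0, 0, 1, 1])
        treats = np.array([0, 0, 0, 0])
        with pytest.raises(DesignError):
            BlockDesignData(blocks, treats, np.arange(4.0))

    def test_null_rejection_rate_calibrated(self):
        # type-I error at alpha = 0.05 stays below 0.07 over seeded nulls
        rng = np.random.default_rng(5)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            table = rng.normal(0, 1, (5, 4, 3))
            d = BlockDesignData(*long_format(table))
            rejections += gore_test(d).p_value < 0.05
        assert rejections / n_sim <= 0.07

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(6)
        rates = []
        for shift in (0.0, 0.6, 1.5):
            rej = 0
            for _ in range(150):
                table = rng.normal(0, 1, (5, 3, 2))
                table[:, 2, :] += shift
                d = BlockDesignData(*long_format(table))
                rej += gore_test(d).p_value < 0.05
            rates.append(rej / 150)
        assert rates[0] <= rates[1] <= rates[2]


class TestSkillingsMack:
    def test_complete_data_equals_tie_corrected_friedman(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            table = np.round(rng.normal(0, 1, (6, 4)), 1)  # rounding makes ties
            d = BlockDesignData(*long_format(table))
            res = skillings_mack_test(d)
            ref = sps.friedmanchisquare(*[table[:, j] for j in range(4)])
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)

    def test_all_equal_gives_zero(self):
        d = BlockDesignData(*long_format(np.ones((4, 3))))
        assert skillings_mack_test(d).statistic == pytest.approx(0.0, abs=1e-12)

    def test_missing_cell_with_extreme_treatment(self):
        # six blocks: enough rank information for p < 0.01 even with a
        # missing cell (a chi-squared rank statistic on 4 complete blocks
        # of 3 treatments is bounded at p ~ 0.018 however separated)
        rng = np.random.default_rng(8)
        table = rng.normal(0, 1, (6, 3))
        table[:, 1] += 10.0
        table[:, 2] += 20.0
        d = BlockDesignData(*long_format(table, missing={(0, 2)}))
        res = skillings_mack_test(d)
        assert res.p_value < 0.01

    def test_replicated_cells_rejected(self):
        table = np.ones((3, 3, 2))
        d = BlockDesignData(*long_format(table))
        with pytest.raises(DesignError):
            skillings_mack_test(d)

    def test_null_rejection_rate_with_missing_cells(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            table = rng.normal(0, 1, (6, 4))
            d = BlockDesignData(*long_format(table, missing={(0, 1), (3, 2)}))
            rejections += skillings_mack_test(d).p_value < 0.05
        assert rejections / n_sim <= 0.07


class TestDunn:
    def test_identical_groups_all_adjusted_to_one(self):
        groups = [np.arange(10.0)] * 4
        res = dunn_posthoc(groups)
        assert all(r.p_value == 1.0 for r in res.values())

    def test_pair_count_and_multiplier_for_six_groups(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(0, 1, 8) for _ in range(6)]
        res = dunn_posthoc(groups)
        assert len(res) == 15
        # adjusted p = min(1, raw * 15): check one pair against raw z
        (pair, r) = next(iter(res.items()))
        raw = 2 * sps.norm.sf(abs(r.statistic))
        assert r.p_value == pytest.approx(min(1.0, raw * 15))

    def test_z_matches_hand_ranks(self):
        a, b, c = [1.0, 2.0], [3.0, 4.0], [5.0, 6.0]
        res = dunn_posthoc([a, b, c], labels=["a", "b", "c"])
        # pooled ranks 1..6 (no ties): mean ranks 1.5, 3.5, 5.5
        # var_unit = 6*7/12 = 3.5; se = sqrt(3.5 * (1/2 + 1/2)) = sqrt(3.5)
        z_ab = (1.5 - 3.5) / np.sqrt(3.5)
        assert res[("a", "b")].statistic == pytest.approx(z_ab)

    def test_requires_three_groups(self):
        with pytest.raises(DesignError):
            dunn_posthoc([np.arange(3.0), np.arange(3.0)])


class TestDistributionTests:
    def test_ks_identical_samples(self):
        x = np.arange(10.0)
        res = ks_two_sample(x, x)
        assert res.statistic == 0.0

    def test_ks_disjoint_samples(self):
        res = ks_two_sample([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 1.0

    def test_ks_null_p_is_roughly_uniform(self):
        # null-calibration oracle; 100 per group keeps the discreteness of
        # the D statistic small enough for the p-values to look uniform
        # (at 50 per group the discrete support alone forces D > 0.12)
        rng = np.random.default_rng(11)
        pvals = [
            ks_two_sample(rng.normal(0, 1, 100), rng.normal(0, 1, 100)).p_value
            for _ in range(500)
        ]
        d = sps.kstest(pvals, "uniform").statistic
        assert d < 0.1

    def test_rank_sum_identical(self):
        x = np.arange(1.0, 9.0)
        assert rank_sum_test(x, x).p_value > 0.9

    def test_rank_sum_matches_exact_enumeration(self):
        # exact null: all C(10,5) labelings of the pooled sample
        from itertools import combinations

        rng = np.random.default_rng(12)
        x = rng.normal(0.8, 1, 5)
        y = rng.normal(0.0, 1, 5)
        res = rank_sum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        obs = ranks[:5].sum()
        mean = 5 * 11 / 2
        count = 0
        total = 0
        for idx in combinations(range(10), 5):
            s = ranks[list(idx)].sum()
            count += abs(s - mean) >= abs(obs - mean) - 1e-9
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=0.01)

    def test_pearson_limits_and_hand_value(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        # hand computation on a small table
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert pearson_r(a, b) == pytest.approx(num / den)


class TestDiffusionKDE:
    def test_density_normalizes(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 2000)
        grid = np.linspace(-6, 6, 801)
        dens = diffusion_kde(x, grid)
        assert np.all(dens >= 0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_gaussian_mise(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 10_000)
        grid = np.linspace(-6, 6, 1001)
        dens = diffusion_kde(x, grid)
        mise = np.trapezoid((dens - sps.norm.pdf(grid)) ** 2, grid)
        assert mise < 5e-3

    def test_bimodal_modes_preserved(self):
        rng = np.random.default_rng(15)
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(6, 1, 5000)])
        grid = np.linspace(-5, 11, 1201)
        dens = diffusion_kde(x, grid)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(dens, height=dens.max() * 0.2)
        assert len(peaks) == 2

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            diffusion_kde(np.ones(100), np.linspace(0, 2, 50))

    def test_agrees_broadly_with_gaussian_kde(self):
        # cross-check against an independent estimator on an easy density
        rng = np.random.default_rng(16)
        x = rng.normal(0, 1, 5000)
        grid = np.linspace(-5, 5, 501)
        d1 = diffusion_kde(x, grid)
        d2 = sps.gaussian_kde(x)(grid)
        assert np.max(np.abs(d1 - d2)) < 0.05


class TestExpTrend:
    def test_exact_data_recovered(self):
        x = np.repeat(np.arange(0.0, 12.0, 2.0), 3)
        y = 5.0 * np.exp(0.15 * x) + 21.0
        fit = fit_exp_trend(x, y, C=21.0)
        assert fit.A == pytest.approx(5.0, abs=1e-8)
        assert fit.B == pytest.approx(0.15, abs=1e-8)
        assert fit.rss < 1e-16

    def test_flat_data_fits_constant(self):
        x = np.repeat(np.arange(0.0, 12.0, 2.0), 3)
        y = np.full_like(x, 26.0)
        fit = fit_exp_trend(x, y, C=21.0)
        pred = fit.predict(x)
        np.testing.assert_allclose(pred, 26.0, atol=1e-6)

    def test_default_C_is_first_timepoint_mean(self):
        x = np.array([0.0, 0.0, 2.0, 4.0, 6.0])
        y = np.array([20.0, 22.0, 25.0, 30.0, 40.0])
        model = ExpTrendModel(x, y)
        assert model.C == pytest.approx(21.0)

    def test_noisy_B_recovery_rate(self):
        # Monte-Carlo oracle: B within +/-0.05 in >= 90% of replicates
        rng = np.random.default_rng(17)
        x = np.repeat(np.arange(0.0, 12.0, 2.0), 5)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = 5.0 * np.exp(0.15 * x) + 21.0 + rng.normal(0, 1, x.size)
            fit = fit_exp_trend(x, y, C=21.0)
            hits += abs(fit.B - 0.15) <= 0.05
        assert hits >= 0.90 * n_rep


class TestModelEquivalenceF:
    def _fit_pair(self, rng, b2=0.15, sigma=0.8):
        x = np.repeat(np.arange(0.0, 12.0, 2.0), 4)
        y1 = 5.0 * np.exp(0.15 * x) + 21.0 + rng.normal(0, sigma, x.size)
        y2 = 5.0 * np.exp(b2 * x) + 21.0 + rng.normal(0, sigma, x.size)
        f1 = fit_exp_trend(x, y1, C=21.0)
        f2 = fit_exp_trend(x, y2, C=21.0)
        return f1, (x, y1), f2, (x, y2)

    def test_same_model_rarely_rejected(self):
        rng = np.random.default_rng(18)
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            r1, r2 = f_test_model_equivalence(*self._fit_pair(rng))
            ok += (r1.p_value > 0.05) and (r2.p_value > 0.05)
        assert ok >= 0.90 * n_rep

    def test_faster_growth_detected(self):
        rng = np.random.default_rng(19)
        detected = 0
        n_rep = 50
        for _ in range(n_rep):
            r1, r2 = f_test_model_equivalence(
                *self._fit_pair(rng, b2=0.30, sigma=0.3)
            )
            detected += (r1.p_value < 0.05) or (r2.p_value < 0.05)
        assert detected >= 0.9 * n_rep

    def test_identical_datasets_give_unit_F_and_maximal_p(self):
        rng = np.random.default_rng(20)
        x = np.repeat(np.arange(0.0, 12.0, 2.0), 3)
        y = 5.0 * np.exp(0.15 * x) + 21.0 + rng.normal(0, 1, x.size)
        f = fit_exp_trend(x, y, C=21.0)
        r1, r2 = f_test_model_equivalence(f, (x, y), f, (x, y))
        assert r1.statistic == pytest.approx(1.0)
        assert r1.p_value == pytest.approx(1.0)

    def test_exact_fit_raises_zero_denominator(self):
        x = np.repeat(np.arange(0.0, 8.0, 2.0), 2)
        y = 2.0 * np.exp(0.1 * x) + 5.0
        f = fit_exp_trend(x, y, C=5.0)
        with pytest.raises(ZeroDivisionError):
            f_test_model_equivalence(f, (x, y), f, (x, y))

    def test_bonferroni_never_decreases_p(self):
        rng = np.random.default_rng(21)
        groups = [rng.normal(0, 1, 6) for _ in range(4)]
        adjusted = dunn_posthoc(groups)
        for r in adjusted.values():
            raw = 2 * sps.norm.sf(abs(r.statistic))
            assert r.p_value >= raw - 1e-12
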