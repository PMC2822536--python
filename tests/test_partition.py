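import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bimodal import (
    DegenerateGeneError,
    ExpressionDataset,
    InsufficientDataError,
    NORMAL_BASELINE_TAU,
    detect_bimodal,
    optimal_partition,
    std_percentile_filter,
    tau_statistic,
    trim_outliers,
)


def brute_force_partition(x):
    """Independent oracle: score every split of the sorted vector directly."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    gammas = []
    for k in range(1, n):
        lo, hi = xs[:k], xs[k:]
        gammas.append(np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2))
    return np.asarray(gammas)


class TestOptimalPartition:
    def test_perfectly_separated(self):
        f = optimal_partition([0, 0, 0, 1, 1, 1])
        assert (f.K, f.l, f.u, f.gamma, f.T) == (3, 0.0, 1.0, 0.0, 0.5)

    def test_worked_example(self):
        # exhaustive scan of [1,2,3,10,11,12]: split after 3 gives SS 2+2=4,
        # every other split >= 50.5
        f = optimal_partition([1, 2, 3, 10, 11, 12])
        assert (f.K, f.l, f.u, f.T) == (3, 2.0, 11.0, 6.5)
        assert f.gamma == pytest.approx(4.0)
        oracle = brute_force_partition([1, 2, 3, 10, 11, 12])
        assert oracle.min() == pytest.approx(4.0)
        assert (oracle[[0, 1, 3, 4]] >= 50.5).all()

    def test_constant_gene_is_degenerate(self):
        with pytest.raises(DegenerateGeneError):
            optimal_partition([5, 5, 5, 5])

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            optimal_partition([1.0])

    def test_order_of_input_is_irrelevant(self, rng):
        x = rng.normal(size=30)
        a, b = optimal_partition(x), optimal_partition(x[::-1])
        assert a.K == b.K and a.gamma == pytest.approx(b.gamma)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=50))
    def test_gamma_matches_exhaustive_scan(self, values):
        """The returned split attains the minimum of the brute-force scan."""
        if np.ptp(values) == 0:
            with pytest.raises(DegenerateGeneError):
                optimal_partition(values)
            return
        fit = optimal_partition(values)
        oracle = brute_force_partition(values)
        tol = 1e-9 * max(1.0, float(oracle.min()))
        assert fit.gamma == pytest.approx(float(oracle.min()), abs=tol)
        assert oracle[fit.K - 1] <= oracle.min() + tol

    @pytest.mark.parametrize("scale,shift", [(1, 0), (2, 5), (4, -3)])
    def test_exact_gamma_ties_take_smallest_k(self, scale, shift):
        """[0,0,1,1,2,2] has exactly tied optimal splits at K=2 and K=4
        (gamma = 1, exactly representable); the smaller K wins."""
        x = scale * np.array([0, 0, 1, 1, 2, 2], dtype=float) + shift
        oracle = brute_force_partition(x)
        assert oracle[1] == oracle[3] == oracle.min()
        assert optimal_partition(x).K == 2

    def test_threshold_sits_between_modes(self, rng):
        for _ in range(20):
            x = rng.normal(size=25)
            f = optimal_partition(x)
            xs = np.sort(x)
            assert xs[f.K - 1] <= f.T <= xs[f.K]
            assert f.l < f.u


class TestTauStatistic:
    def test_worked_example(self):
        f = optimal_partition([1, 2, 3, 10, 11, 12])
        assert tau_statistic(f, 6) == pytest.approx(9 / math.sqrt(4 / 6), rel=1e-12)

    def test_zero_gamma_gives_infinity(self):
        f = optimal_partition([0, 0, 0, 1, 1, 1])
        assert tau_statistic(f, 6) == math.inf

    def test_normal_baseline_closed_form(self):
        assert NORMAL_BASELINE_TAU == pytest.approx(2.6472, abs=5e-4)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.01, 100),
        b=st.floats(-100, 100),
    )
    def test_affine_invariance(self, seed, a, b):
        """tau(a*x + b) == tau(x) for a > 0: both u-l and sqrt(gamma/M) scale by a."""
        x = np.random.default_rng(seed).normal(size=40)
        t0 = tau_statistic(optimal_partition(x), 40)
        t1 = tau_statistic(optimal_partition(a * x + b), 40)
        assert t1 == pytest.approx(t0, rel=1e-9)

    def test_monotone_in_mode_separation(self, rng):
        """Widening the gap between two planted modes never decreases tau."""
        noise = rng.normal(0, 0.5, 100)
        modes = rng.random(100) < 0.5
        taus = []
        for gap in (1.0, 2.0, 4.0, 8.0):
            x = noise + np.where(modes, gap / 2, -gap / 2)
            taus.append(tau_statistic(optimal_partition(x), 100))
        assert all(t2 >= t1 for t1, t2 in zip(taus, taus[1:]))


class TestTrimOutliers:
    def test_three_extreme_of_hundred_flagged(self, rng):
        x = rng.normal(0, 1, 100)
        x[[10, 40, 80]] += 25.0
        trimmed, outliers = trim_outliers(x, fraction=0.05)
        assert outliers == [10, 40, 80]
        assert trimmed.size == 97

    def test_balanced_modes_untouched(self, rng):
        x = np.concatenate([rng.normal(-2, 0.3, 50), rng.normal(2, 0.3, 50)])
        trimmed, outliers = trim_outliers(x, fraction=0.05)
        assert outliers == [] and trimmed.size == 100

    def test_fraction_zero_is_identity(self, rng):
        x = rng.normal(size=50)
        trimmed, outliers = trim_outliers(x, fraction=0.0)
        assert outliers == []
        np.testing.assert_array_equal(trimmed, x)

    def test_idempotent_once_clean(self, rng):
        x = rng.normal(0, 1, 100)
        x[:4] += 30.0
        trimmed, outliers = trim_outliers(x, fraction=0.05)
        again, more = trim_outliers(trimmed, fraction=0.05)
        assert more == []
        np.testing.assert_array_equal(again, trimmed)

    def test_survivor_floor(self):
        with pytest.raises(InsufficientDataError):
            trim_outliers([1.0, 2.0, 3.0], fraction=0.05)


class TestStdPercentileFilter:
    @staticmethod
    def _dataset(stds, n=40, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 1, n)
        base = base / base.std(ddof=1)
        # identical shape per gene, scaled: per-gene stds are exactly `stds`
        # up to one ulp, with all-equal rows bit-identical
        values = np.array([base * s for s in stds])
        return ExpressionDataset(
            [f"g{i}" for i in range(len(stds))], [f"s{j}" for j in range(n)], values
        )

    def test_linear_interpolation_threshold(self):
        # percentile_25([1,2,3,4]) = 1.75 -> stds 2,3,4 pass strictly
        ds = self._dataset([1, 2, 3, 4])
        assert std_percentile_filter(ds, 25) == {"g1", "g2", "g3"}

    def test_percentile_zero_passes_all_above_min(self):
        ds = self._dataset([1, 2, 3, 4])
        assert std_percentile_filter(ds, 0) == {"g1", "g2", "g3"}

    def test_all_equal_stds_pass_nothing(self):
        ds = self._dataset([2, 2, 2, 2])
        assert std_percentile_filter(ds, 25) == set()


class TestDetectBimodal:
    def test_planted_two_mode_gene_is_called(self, rng):
        n = 200
        values = rng.normal(0, 0.5, (20, n))
        modes = rng.random(n) < 0.5
        values[0] += np.where(modes, 2.0, -2.0)
        ds = ExpressionDataset(
            [f"g{i}" for i in range(20)], [f"s{j}" for j in range(n)], values
        )
        fits = detect_bimodal(ds)
        assert fits[0].is_bimodal and fits[0].tau > 2.64
        assert fits[0].flag == "ok"

    def test_constant_gene_flagged_not_raised(self, rng):
        values = rng.normal(size=(3, 30))
        values[1] = 4.2
        ds = ExpressionDataset(["a", "b", "c"], [f"s{j}" for j in range(30)], values)
        fits = detect_bimodal(ds)
        assert fits[1].flag == "degenerate" and not fits[1].is_bimodal

    def test_short_gene_flagged_insufficient(self, rng):
        values = rng.normal(size=(3, 30))
        values[2, 8:] = np.nan
        ds = ExpressionDataset(["a", "b", "c"], [f"s{j}" for j in range(30)], values)
        fits = detect_bimodal(ds, min_samples=10)
        assert fits[2].flag == "insufficient_data"

    def test_null_flag_rate_matches_monte_carlo_oracle(self):
        """On an all-iid-normal dataset the flagged fraction equals
        P(null tau > 2.64) x P(std above its 25th percentile), estimated
        independently; the tau cutoff alone admits over half of null genes."""
        rng = np.random.default_rng(5)
        n_genes, M = 400, 200
        ds = ExpressionDataset(
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(M)],
            rng.standard_normal((n_genes, M)),
        )
        flagged = np.mean([f.is_bimodal for f in detect_bimodal(ds)])
        # independent oracle: tau and std are independent under the null
        # (tau is affine-invariant), so expect P(tau > 2.64) * 0.75
        oracle_rng = np.random.default_rng(99)
        taus = [
            tau_statistic(optimal_partition(oracle_rng.standard_normal(M)), M)
            for _ in range(600)
        ]
        expected = np.mean(np.asarray(taus) > 2.64) * 0.75
        assert flagged == pytest.approx(expected, abs=0.07)
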