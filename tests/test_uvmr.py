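"""Univariable estimators against hand computations and WLS/percentile/KDE oracles."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from mrmediate.exceptions import DegenerateInstrumentError, InsufficientInstrumentsError
from mrmediate.uvmr import (
    cochran_q,
    ivw,
    leave_one_out,
    mean_f_statistic,
    mode_estimate,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)

from conftest import make_harmonized, random_harmonized


class TestWaldRatio:
    def test_first_order_division(self):
        est = wald_ratio(0.5, 0.01, 0.25, 0.05, "first")
        assert est.ratio == pytest.approx(0.5)
        assert est.se_ratio == pytest.approx(0.1)
        assert est.weight == pytest.approx(est.se_ratio**-2)

    def test_zero_numerator(self):
        est = wald_ratio(1.0, 0.01, 0.0, 0.1, "first")
        assert est.ratio == 0.0
        assert est.se_ratio == pytest.approx(0.1)

    def test_second_order_propagation(self):
        est = wald_ratio(2.0, 0.1, 1.0, 0.2, "second")
        assert est.se_ratio == pytest.approx(math.sqrt(0.010625))

    def test_zero_gamma_raises_naming_snp(self):
        with pytest.raises(DegenerateInstrumentError, match="rsX"):
            wald_ratio(0.0, 0.01, 0.1, 0.05, variant_id="rsX")


class TestIVW:
    def test_homogeneous_ratios_give_zero_q(self):
        H = make_harmonized([0.1, 0.2, 0.4], 0.01, [0.04, 0.08, 0.16], [0.01, 0.02, 0.04])
        est = ivw(H)
        assert est.beta == pytest.approx(0.4)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)
        assert ivw(H, "fixed").se == pytest.approx(est.se)  # no inflation when Q=0

    def test_two_snp_hand_computation(self):
        # ratios {1, 3} with unit ratio SEs: beta 2, fixed se 1/sqrt(2), Q=2
        H = make_harmonized([1.0, 1.0], 0.01, [1.0, 3.0], [1.0, 1.0])
        fixed = ivw(H, "fixed")
        rand = ivw(H, "multiplicative_random")
        assert fixed.beta == pytest.approx(2.0)
        assert fixed.se == pytest.approx(1 / math.sqrt(2))
        assert fixed.q_stat == pytest.approx(2.0)
        assert rand.se == pytest.approx(1.0)  # (1/sqrt 2)·sqrt(2/1)

    def test_equals_wls_through_origin(self, rng):
        H = random_harmonized(rng, 40)
        est = ivw(H)
        fit = sm.WLS(H.gamma_out, H.gamma, weights=H.se_gamma_out**-2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_sign_flip_invariance(self, rng):
        H = random_harmonized(rng, 15)
        flipped = H.df.copy()
        flipped.loc[3, ["gamma", "gamma_out"]] *= -1
        from mrmediate.summary_io import HarmonizedSet

        H2 = HarmonizedSet(flipped, H.exposure_label, H.outcome_label)
        assert ivw(H2).beta == pytest.approx(ivw(H).beta, abs=1e-12)

    def test_equal_weights_reduce_to_mean(self):
        H = make_harmonized([1.0, 1.0, 1.0], 0.01, [1.0, 2.0, 6.0], 1.0)
        assert ivw(H).beta == pytest.approx(3.0)

    def test_single_snp_falls_back_to_wald_ratio(self):
        H = make_harmonized([0.5], 0.01, [0.25], [0.05])
        est = ivw(H)
        assert est.method == "WaldRatio"
        assert est.beta == pytest.approx(0.5)


class TestEgger:
    def test_exact_line_recovered(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        H = make_harmonized(g, 0.01, 0.02 + 0.3 * g, 0.01)
        est = mr_egger(H)
        assert est.intercept == pytest.approx(0.02, abs=1e-12)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_intercept_free_data_matches_ivw_slope(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        H = make_harmonized(g, 0.01, 0.3 * g, 0.01)
        est = mr_egger(H)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(ivw(H).beta, abs=1e-10)

    def test_equals_generic_wls_with_orientation(self, rng):
        H = random_harmonized(rng, 30)
        df = H.df.copy()
        df.loc[::3, ["gamma", "gamma_out"]] *= -1  # scatter negative gammas
        from mrmediate.summary_io import HarmonizedSet

        H2 = HarmonizedSet(df, "x", "y")
        est = mr_egger(H2)
        s = np.where(H2.gamma < 0, -1.0, 1.0)
        X = sm.add_constant(s * H2.gamma)
        fit = sm.WLS(s * H2.gamma_out, X, weights=H2.se_gamma_out**-2).fit()
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_needs_three_snps(self):
        H = make_harmonized([0.1, 0.2], 0.01, [0.03, 0.06], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(H)


def brute_force_weighted_percentile(ratios, weights, q=0.5):
    """Scan the sorted list accumulating weight mass (independent of the
    vectorized implementation)."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    acc = 0.0
    for i, (r, w) in enumerate(pairs):
        prev = acc
        acc += w / total
        if acc > q:
            return r
        if acc == q:
            return 0.5 * (r + pairs[i + 1][0])
    return pairs[-1][0]


class TestWeightedMedian:
    def test_all_equal_ratios(self):
        assert weighted_median_point(np.array([0.7] * 5), np.ones(5)) == 0.7

    def test_plain_median_with_equal_weights(self):
        assert weighted_median_point(np.array([1.0, 2.0, 9.0]), np.ones(3)) == 2.0

    def test_dominant_weight_case_matches_oracle(self):
        r, w = np.array([1.0, 2.0, 3.0]), np.array([0.6, 0.2, 0.2])
        est = weighted_median_point(r, w)
        assert 1.0 <= est <= 2.0
        assert est == brute_force_weighted_percentile(r, w)

    def test_majority_weight_on_shared_ratio_returns_it_exactly(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            k = int(rng.integers(2, n - 1))
            shared = float(rng.normal())
            r = np.concatenate([np.full(k, shared), rng.normal(5, 1, n - k)])
            w = rng.uniform(0.1, 1.0, n)
            w[:k] *= (w[k:].sum() / w[:k].sum()) * 1.5  # >50% of weight on the shared ratio
            assert weighted_median_point(r, w) == shared

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_brute_force_on_random_instances(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(3, 30))
        r = rng.normal(0, 2, n)
        w = rng.uniform(0.01, 1.0, n)
        assert weighted_median_point(r, w) == pytest.approx(
            brute_force_weighted_percentile(r, w), abs=1e-12
        )

    def test_full_estimator_is_seed_reproducible(self, rng):
        H = random_harmonized(rng, 20)
        a = weighted_median(H, n_boot=200, seed=7)
        b = weighted_median(H, n_boot=200, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)
        assert a.se > 0


def kde_argmax_oracle(ratios, kernel_weights, h, grid_size=20001):
    """Dense-grid argmax with scipy's normal pdf."""
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = (sps.norm.pdf((grid[:, None] - ratios[None, :]) / h) * kernel_weights).sum(axis=1)
    return grid[np.argmax(dens)]


class TestModeEstimate:
    def test_degenerate_density_returns_common_ratio(self):
        H = make_harmonized([0.1, 0.2, 0.4], 0.01, [0.07, 0.14, 0.28], [0.01, 0.02, 0.04])
        est = mode_estimate(H, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.7)

    def test_majority_cluster_wins_with_equal_weights(self):
        g = np.ones(4) * 0.1
        ratios = np.array([0.99, 1.00, 1.01, 5.0])
        H = make_harmonized(g, 0.01, ratios * g, 0.001)
        est = mode_estimate(H, weighted=False, phi=1.0, n_boot=100, seed=1)
        assert abs(est.beta - 1.0) < 0.05
        # and it agrees with an independent dense-grid KDE argmax
        from mrmediate.uvmr import _mode_bandwidth

        h = _mode_bandwidth(ratios, 1.0)
        assert est.beta == pytest.approx(
            kde_argmax_oracle(ratios, np.full(4, 0.25), h), abs=0.01
        )

    def test_heavy_weight_moves_weighted_mode(self):
        g = np.ones(4) * 0.1
        ratios = np.array([0.99, 1.00, 1.01, 5.0])
        se_out = np.array([0.02, 0.02, 0.02, 0.02 / math.sqrt(0.94 / 0.02)])
        H = make_harmonized(g, 0.01, ratios * g, se_out)
        w = (se_out / g) ** -2
        assert w[3] / w.sum() > 0.9
        est = mode_estimate(H, weighted=True, phi=1.0, n_boot=100, seed=1)
        assert abs(est.beta - 5.0) < 0.05

    def test_simple_mode_ignores_weights(self):
        g = np.ones(4) * 0.1
        ratios = np.array([0.99, 1.00, 1.01, 5.0])
        se_out = np.array([0.02, 0.02, 0.02, 0.002])
        H = make_harmonized(g, 0.01, ratios * g, se_out)
        est = mode_estimate(H, weighted=False, phi=1.0, n_boot=100, seed=1)
        assert abs(est.beta - 1.0) < 0.05


class TestDiagnostics:
    def test_cochran_q_homogeneous(self):
        H = make_harmonized([0.1, 0.2], 0.01, [0.04, 0.08], [0.01, 0.02])
        q, df, p = cochran_q(H, 0.4)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_cochran_q_hand_case_and_chi2_tail(self):
        H = make_harmonized([1.0, 1.0], 0.01, [1.0, 3.0], [1.0, 1.0])
        q, df, p = cochran_q(H, 2.0)
        assert q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(2.0, 1))

    def test_mean_f_values_and_quadratic_scaling(self):
        H = make_harmonized([0.1], [0.01], [0.0], [0.1])
        assert mean_f_statistic(H) == pytest.approx(100.0)
        H2 = make_harmonized([0.1, 0.06], [0.01, 0.01], [0.0, 0.0], 0.1)
        assert mean_f_statistic(H2) == pytest.approx((100 + 36) / 2)
        H3 = make_harmonized([0.1, 0.06], [0.02, 0.02], [0.0, 0.0], 0.1)
        assert mean_f_statistic(H3) == pytest.approx((100 + 36) / 8)


class TestLeaveOneOut:
    def test_homogeneous_set_rows_equal_full_estimate(self):
        g = np.linspace(0.1, 0.5, 6)
        H = make_harmonized(g, 0.01, 0.4 * g, 0.01)
        table = leave_one_out(H)
        assert len(table) == 6
        assert np.allclose(table["beta"], ivw(H).beta)

    def test_planted_outlier_row_is_extreme_and_best(self, rng):
        # exact proportional data (Gamma = 0.3·gamma) with one SNP displaced
        # upward by 10 sampling SDs: only its exclusion restores the truth
        g = rng.uniform(0.05, 0.2, 12)
        se_out = np.full(12, 0.01)
        G = 0.3 * g
        G[7] += 10 * se_out[7]
        from mrmediate.summary_io import HarmonizedSet
        import pandas as pd

        H = make_harmonized(g, 0.01, G, se_out)
        table = leave_one_out(H).set_index("excluded_snp")
        outlier_id = H.variant_ids[7]
        assert table.loc[outlier_id, "beta"] == pytest.approx(0.3, abs=1e-12)
        others = table.drop(outlier_id)["beta"]
        # every other exclusion keeps the upward bias
        assert (others > 0.3 + 1e-6).all()
        assert table.loc[outlier_id, "beta"] == table["beta"].min()
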