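"""The five MR estimators against hand arithmetic and independent oracles."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_hset, random_hset
from mrkit.estimators import (
    EggerRegression,
    IVWEstimator,
    ModeEstimator,
    WeightedMedianEstimator,
    run_all_methods,
    wald_ratio,
)
from mrkit.exceptions import InputError, InsufficientInstrumentsError


def wls_oracle(X, y, w):
    """Independently coded weighted least squares via a scaled lstsq."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def weighted_median_oracle(values, weights):
    """Brute-force weighted quantile: walk the cumulative midpoints.

    Ties are kept in input order (stable sort), matching the estimator's
    deterministic tie rule.
    """
    order = np.argsort(values, kind="mergesort")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    mid = np.cumsum(w) - w / 2
    if 0.5 <= mid[0]:
        return v[0]
    for i in range(1, len(v)):
        if mid[i] >= 0.5:
            frac = (0.5 - mid[i - 1]) / (mid[i] - mid[i - 1])
            return v[i - 1] + frac * (v[i] - v[i - 1])
    return v[-1]


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(0.2, 0.02, 0.1, 0.02)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_effect_gives_p_one(self):
        est = wald_ratio(1.0, 0.1, 0.0, 0.1)
        assert est.theta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_zero_gamma_rejected(self):
        with pytest.raises(InputError):
            wald_ratio(0.0, 0.1, 0.1, 0.1)

    def test_se_close_to_finite_difference_delta_oracle(self, rng):
        # numerical propagation of (gamma, Gamma) uncertainty through the
        # ratio; the first-order se is valid in the strong-instrument,
        # moderate-effect regime (sigma_X << |gamma|, |theta| of order 1)
        for _ in range(50):
            gamma = rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
            Gamma = rng.uniform(-1.0, 1.0) * gamma
            sy = rng.uniform(0.01, 0.05)
            sx = sy / 5
            eps = 1e-6
            d_gamma = ((Gamma / (gamma + eps)) - (Gamma / (gamma - eps))) / (2 * eps)
            d_Gamma = 1.0 / gamma
            full_se = np.sqrt(d_gamma**2 * sx**2 + d_Gamma**2 * sy**2)
            est = wald_ratio(gamma, sx, Gamma, sy)
            assert est.se == pytest.approx(full_se, rel=0.10)


class TestIVW:
    def test_hand_arithmetic_case(self):
        h = make_hset([1.0, 1.0], [0.1, 0.1], [0.4, 0.6], [0.1, 0.1])
        fit = IVWEstimator(effects_model="fixed").fit_set(h)
        assert fit.effect_ == pytest.approx(0.5)
        assert fit.se_ == pytest.approx(np.sqrt(1 / 200))

    def test_single_instrument_collapses_to_wald_ratio_bitwise(self):
        h = make_hset([0.137], [0.021], [0.053], [0.017])
        fit = IVWEstimator().fit_set(h)
        wald = wald_ratio(0.137, 0.021, 0.053, 0.017)
        assert fit.effect_ == wald.theta  # exact, not approx
        assert fit.se_ == wald.se

    def test_matches_wls_through_origin_oracle(self):
        for seed in range(100):
            h = random_hset(np.random.default_rng(seed))
            w = 1.0 / h.se_outcome**2
            coef = wls_oracle(h.beta_exposure[:, None], h.beta_outcome, w)
            fit = IVWEstimator(effects_model="fixed").fit_set(h)
            assert fit.effect_ == pytest.approx(coef[0], abs=1e-10)

    def test_random_effects_never_shrinks_se(self, rng):
        h = random_hset(rng)
        fixed = IVWEstimator(effects_model="fixed").fit_set(h)
        random_fx = IVWEstimator().fit_set(h)
        assert random_fx.se_ >= fixed.se_
        assert random_fx.effect_ == fixed.effect_


class TestEgger:
    def test_collinear_points_recover_slope_and_intercept_exactly(self):
        h = make_hset([1, 2, 3], [0.1] * 3, [1.5, 2.5, 3.5], [0.1] * 3)
        fit = EggerRegression().fit_set(h)
        assert fit.effect_ == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept_ == pytest.approx(0.5, abs=1e-12)

    def test_matches_wls_with_intercept_oracle(self):
        for seed in range(100):
            h = random_hset(np.random.default_rng(seed))
            flip = np.where(h.beta_exposure < 0, -1.0, 1.0)
            x = flip * h.beta_exposure
            y = flip * h.beta_outcome
            w = 1.0 / h.se_outcome**2
            X = np.column_stack([np.ones_like(x), x])
            coef = wls_oracle(X, y, w)
            fit = EggerRegression().fit_set(h)
            assert fit.intercept_ == pytest.approx(coef[0], abs=1e-10)
            assert fit.effect_ == pytest.approx(coef[1], abs=1e-10)

    def test_standard_errors_match_statsmodels_when_inflation_active(self, rng):
        import statsmodels.api as sm

        h = random_hset(rng, J=30)
        flip = np.where(h.beta_exposure < 0, -1.0, 1.0)
        X = sm.add_constant(flip * h.beta_exposure)
        res = sm.WLS(flip * h.beta_outcome, X, weights=1.0 / h.se_outcome**2).fit()
        fit = EggerRegression().fit_set(h)
        if res.scale >= 1.0:  # our variance uses max(1, RSS/(J-2))
            assert fit.se_ == pytest.approx(res.bse[1], rel=1e-8)
            assert fit.intercept_se_ == pytest.approx(res.bse[0], rel=1e-8)

    def test_requires_three_instruments(self):
        h = make_hset([0.1, 0.2], [0.02] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            EggerRegression().fit_set(h)


class TestWeightedMedian:
    def test_equal_weight_odd_count_is_middle_ratio(self):
        # ratios 0.1, 0.2, 0.9 with equal ratio-scale weights
        h = make_hset([1, 1, 1], [0.1] * 3, [0.1, 0.2, 0.9], [0.1] * 3)
        fit = WeightedMedianEstimator(n_boot=50, random_state=0).fit_set(h)
        assert fit.effect_ == pytest.approx(0.2)

    def test_specified_weights_interpolation_case(self):
        # ratios (1,2,3), normalized weights (0.2,0.3,0.5):
        # midpoints 0.1/0.35/0.75 -> interpolate 0.5 -> 2.375
        sy = 1.0 / np.sqrt([0.2, 0.3, 0.5])
        h = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 3.0], sy)
        fit = WeightedMedianEstimator(n_boot=50, random_state=0).fit_set(h)
        assert fit.effect_ == pytest.approx(2.375)

    def test_matches_brute_force_oracle_on_random_sets(self):
        for seed in range(50):
            h = random_hset(np.random.default_rng(seed))
            ratios = h.beta_outcome / h.beta_exposure
            weights = (h.beta_exposure / h.se_outcome) ** 2
            fit = WeightedMedianEstimator(n_boot=10, random_state=0).fit_set(h)
            assert fit.effect_ == pytest.approx(
                weighted_median_oracle(ratios, weights), abs=1e-12
            )

    def test_equal_weights_reduce_to_interpolated_median(self, rng):
        ratios = rng.normal(0.5, 0.2, 11)
        assert weighted_median_oracle(ratios, np.ones(11)) == pytest.approx(
            np.median(ratios)
        )

    def test_bootstrap_se_is_seed_deterministic(self, rng):
        h = random_hset(rng)
        a = WeightedMedianEstimator(n_boot=100, random_state=7).fit_set(h)
        b = WeightedMedianEstimator(n_boot=100, random_state=7).fit_set(h)
        c = WeightedMedianEstimator(n_boot=100, random_state=8).fit_set(h)
        assert a.se_ == b.se_
        assert a.se_ != c.se_


class TestModeEstimators:
    def test_point_mass_returns_common_ratio(self):
        h = make_hset([1, 2, 4], [0.1] * 3, [0.4, 0.8, 1.6], [0.1] * 3)
        fit = ModeEstimator(weighted=False, n_boot=20, random_state=0).fit_set(h)
        assert fit.effect_ == pytest.approx(0.4)

    def test_bimodal_ratios_pick_heavier_cluster(self, rng):
        # 60% of instruments cluster tightly at ratio 0.2, 40% at 0.9
        g = np.ones(10)
        ratios = np.concatenate(
            [0.2 + 0.005 * rng.standard_normal(6), 0.9 + 0.005 * rng.standard_normal(4)]
        )
        h = make_hset(g, [0.01] * 10, ratios, [0.05] * 10)
        fit = ModeEstimator(weighted=False, n_boot=20, random_state=0).fit_set(h)
        assert abs(fit.effect_ - 0.2) < 0.05

        # dense-grid oracle: the argmax over a fine grid agrees
        def density(x, pts, hband):
            z = (x[:, None] - pts[None, :]) / hband
            return np.exp(-0.5 * z**2).sum(axis=1)

        est = ModeEstimator(weighted=False)
        hband = est._bandwidth(ratios)
        grid = np.linspace(ratios.min() - 3 * hband, ratios.max() + 3 * hband, 20001)
        oracle = grid[np.argmax(density(grid, ratios, hband))]
        assert fit.effect_ == pytest.approx(oracle, abs=1e-3)

    def test_simple_and_weighted_modes_coincide_under_equal_weights(self, rng):
        g = np.ones(8)
        G = rng.normal(0.3, 0.1, 8)
        h = make_hset(g, [0.01] * 8, G, [0.05] * 8)  # equal ratio weights
        simple = ModeEstimator(weighted=False, n_boot=10, random_state=0).fit_set(h)
        weighted = ModeEstimator(weighted=True, n_boot=10, random_state=0).fit_set(h)
        assert simple.effect_ == pytest.approx(weighted.effect_, abs=1e-10)


class TestRunAllMethods:
    def test_full_set_runs_all_five_methods_in_order(self, rng):
        h = random_hset(rng, J=10)
        estimates, skipped = run_all_methods(h, n_boot=20, seed=0)
        assert [e.method for e in estimates] == [
            "ivw", "egger", "weighted_median", "simple_mode", "weighted_mode",
        ]
        assert skipped == []

    def test_two_snp_set_runs_ivw_only_with_four_skip_records(self):
        h = make_hset([0.1, 0.2], [0.02] * 2, [0.05, 0.1], [0.02] * 2)
        estimates, skipped = run_all_methods(h, n_boot=20, seed=0)
        assert [e.method for e in estimates] == ["ivw"]
        assert len(skipped) == 4

    def test_degenerate_homogeneous_ratios_agree_across_methods(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        h = make_hset(g, [0.01] * 4, 0.3 * g, [0.05] * 4)
        estimates, _ = run_all_methods(h, n_boot=20, seed=0)
        for est in estimates:
            assert est.theta == pytest.approx(0.3, abs=1e-8)


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_sign_equivariance_negating_outcome_negates_theta(self, seed):
        h = random_hset(np.random.default_rng(seed))
        neg = make_hset(
            h.beta_exposure, h.se_exposure, -h.beta_outcome, h.se_outcome
        )
        for est_a, est_b in [
            (IVWEstimator().fit_set(h), IVWEstimator().fit_set(neg)),
            (EggerRegression().fit_set(h), EggerRegression().fit_set(neg)),
        ]:
            assert est_b.effect_ == pytest.approx(-est_a.effect_, abs=1e-12)
            assert est_b.se_ == pytest.approx(est_a.se_, abs=1e-12)
        # the weighted-median point estimate flips exactly; its bootstrap se
        # is only distributionally symmetric (the resampled noise is not
        # negated along with the effects)
        wm_a = WeightedMedianEstimator(n_boot=200, random_state=3).fit_set(h)
        wm_b = WeightedMedianEstimator(n_boot=200, random_state=3).fit_set(neg)
        assert wm_b.effect_ == pytest.approx(-wm_a.effect_, abs=1e-12)
        assert wm_b.se_ == pytest.approx(wm_a.se_, rel=0.3)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance_of_regression_slopes(self, c, rng):
        h = random_hset(rng)
        scaled = make_hset(
            c * h.beta_exposure, c * h.se_exposure, h.beta_outcome, h.se_outcome
        )
        assert IVWEstimator().fit_set(scaled).effect_ == pytest.approx(
            IVWEstimator().fit_set(h).effect_ / c, rel=1e-10
        )
        assert EggerRegression().fit_set(scaled).effect_ == pytest.approx(
            EggerRegression().fit_set(h).effect_ / c, rel=1e-10
        )

    def test_or_is_exponentiated_theta_with_ordered_ci(self, rng):
        h = random_hset(rng)
        est = IVWEstimator().fit_set(h).estimate_
        assert est.or_value == pytest.approx(np.exp(est.theta))
        assert est.ci_low <= est.theta <= est.ci_high
        assert est.or_low <= est.or_value <= est.or_high


@given(
    st.lists(st.floats(-5, 5), min_size=3, max_size=15),
    st.lists(st.floats(0.1, 3), min_size=3, max_size=15),
)
def test_weighted_quantile_oracle_agreement(values, weights):
    n = min(len(values), len(weights))
    values = np.asarray(values[:n])
    weights = np.asarray(weights[:n])
    from mrkit.estimators import _weighted_quantile

    assert _weighted_quantile(values, weights, 0.5) == pytest.approx(
        weighted_median_oracle(values, weights), abs=1e-12
    )
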