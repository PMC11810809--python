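"""Causal estimators: closed-form cases, independent oracles, invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpath.errors import InsufficientInstrumentsError, UndefinedRatioError
from mrpath.mr_estimators import (
    egger,
    ivw,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_pair, make_pairs


class TestWaldRatio:
    def test_formula(self):
        est = wald_ratio(make_pair(beta_exp=0.2, beta_out=0.1, se_out=0.02))
        assert est.ratio == pytest.approx(0.5)
        assert est.se_ratio == pytest.approx(0.1)

    def test_double_sign_flip_invariance(self):
        a = wald_ratio(make_pair(beta_exp=0.2, beta_out=0.1))
        b = wald_ratio(make_pair(beta_exp=-0.2, beta_out=-0.1))
        assert a.ratio == b.ratio and a.se_ratio == b.se_ratio

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(make_pair(beta_exp=0.0))


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        pair = make_pair(beta_exp=0.2, beta_out=0.1, se_out=0.02)
        est = ivw([pair])
        wald = wald_ratio(pair)
        assert est.method == "wald"
        assert est.beta == pytest.approx(wald.ratio)
        assert est.se == pytest.approx(wald.se_ratio)

    def test_two_identical_snps_degenerate_meta_analysis(self):
        pairs = make_pairs([0.2, 0.2], [0.1, 0.1], 0.02)
        fixed = ivw(pairs, mode="fixed")
        mre = ivw(pairs, mode="multiplicative_random")
        assert fixed.beta == pytest.approx(0.5)
        assert fixed.aux["q"] == pytest.approx(0.0)
        assert mre.se == pytest.approx(fixed.se)  # inflation floored at 1

    def test_matches_weighted_least_squares_oracle(self, rng):
        """IVW equals the statsmodels WLS origin-regression solution."""
        for _ in range(5):
            k = int(rng.integers(3, 11))
            bx = rng.normal(0.1, 0.05, k)
            by = rng.normal(0.05, 0.03, k)
            sy = rng.uniform(0.01, 0.05, k)
            pairs = make_pairs(bx, by, sy)
            est = ivw(pairs, mode="fixed")
            fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_ivw_is_weighted_mean_of_wald_ratios(self, rng):
        bx = rng.normal(0.1, 0.03, 8)
        by = rng.normal(0.05, 0.02, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        pairs = make_pairs(bx, by, sy)
        ratios = np.array([wald_ratio(p).ratio for p in pairs])
        ws = np.array([1 / wald_ratio(p).se_ratio**2 for p in pairs])
        assert ivw(pairs).beta == pytest.approx(
            float(np.sum(ws * ratios) / np.sum(ws)), abs=1e-12
        )

    def test_random_effects_inflates_se_under_heterogeneity(self):
        pairs = make_pairs([0.2, 0.2, 0.2, 0.2], [0.2, 0.05, -0.1, 0.15], 0.01)
        fixed = ivw(pairs, mode="fixed")
        mre = ivw(pairs, mode="multiplicative_random")
        assert mre.se > fixed.se
        assert mre.beta == pytest.approx(fixed.beta)

    def test_all_zero_exposure_effects_undefined(self):
        with pytest.raises(UndefinedRatioError):
            ivw(make_pairs([0.0, 0.0], [0.1, 0.1], 0.02))


class TestEgger:
    def test_recovers_slope_with_negligible_noise(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        pairs = make_pairs(bx, 0.4 * bx + rng.normal(0, 1e-6, 10), 0.01)
        est = egger(pairs)
        assert est.beta == pytest.approx(0.4, abs=1e-3)
        assert est.aux["intercept_pval"] > 0.05

    def test_constant_shift_appears_in_intercept(self, rng):
        """Adding +0.05 to every outcome beta of a null dataset is pure
        directional pleiotropy and lands in the intercept."""
        bx = rng.uniform(0.05, 0.3, 12)
        pairs = make_pairs(bx, 0.05 + rng.normal(0, 1e-6, 12), 0.01)
        est = egger(pairs)
        assert est.aux["egger_intercept"] == pytest.approx(0.05, abs=1e-3)
        assert abs(est.beta) < 1e-2

    def test_orientation_invariance(self, rng):
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.3 * bx + rng.normal(0, 0.01, 8)
        pairs = make_pairs(bx, by, 0.02)
        flipped = make_pairs(
            np.concatenate([[-bx[0]], bx[1:]]),
            np.concatenate([[-by[0]], by[1:]]),
            0.02,
        )
        a, b = egger(pairs), egger(flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.aux["egger_intercept"] == pytest.approx(b.aux["egger_intercept"])

    def test_matches_wls_with_intercept_oracle(self, rng):
        bx = rng.uniform(0.05, 0.3, 9)
        by = 0.02 + 0.3 * bx + rng.normal(0, 0.02, 9)
        sy = rng.uniform(0.01, 0.04, 9)
        pairs = make_pairs(bx, by, sy)
        est = egger(pairs)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.aux["egger_intercept"] == pytest.approx(fit.params[0], abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_pairs([0.1, 0.2], [0.05, 0.1], 0.02))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        pairs = make_pairs([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], 0.02)
        est = weighted_median(pairs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_dominant_weight_pulls_to_that_ratio(self):
        pairs = make_pairs([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], [1e-5, 0.5, 0.5])
        est = weighted_median(pairs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(1.0, abs=1e-3)

    def test_matches_cumulative_weight_oracle(self, rng):
        """Interpolated estimate equals a direct re-implementation."""
        bx = rng.uniform(0.05, 0.3, 5)
        by = rng.normal(0.05, 0.05, 5)
        sy = rng.uniform(0.01, 0.05, 5)
        est = weighted_median(make_pairs(bx, by, sy), n_boot=10, seed=0)

        ratios = by / bx
        w = (np.abs(bx) / sy) ** 2
        w = w / w.sum()
        order = np.argsort(ratios)
        r_sorted, w_sorted = ratios[order], w[order]
        cum = np.cumsum(w_sorted) - 0.5 * w_sorted
        if 0.5 <= cum[0]:
            expected = r_sorted[0]
        else:
            i = np.searchsorted(cum, 0.5)
            frac = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
            expected = r_sorted[i - 1] + frac * (r_sorted[i] - r_sorted[i - 1])
        assert est.beta == pytest.approx(float(expected), abs=1e-12)

    def test_estimate_within_ratio_range(self, rng):
        bx = rng.uniform(0.05, 0.3, 7)
        by = rng.normal(0, 0.05, 7)
        pairs = make_pairs(bx, by, 0.02)
        est = weighted_median(pairs, n_boot=20, seed=2)
        ratios = by / bx
        assert ratios.min() <= est.beta <= ratios.max()

    def test_seed_reproducibility(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.05, 0.1, 0.2], 0.02)
        a = weighted_median(pairs, n_boot=100, seed=7)
        b = weighted_median(pairs, n_boot=100, seed=7)
        assert a.se == b.se


class TestWeightedMode:
    def test_identical_ratios_returned_exactly(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.05, 0.1, 0.2], 0.02)
        est = weighted_mode(pairs, n_boot=20, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_majority_mode_wins(self):
        pairs = make_pairs([0.1] * 4, [0.0, 0.0, 0.0, 0.1], [0.02] * 4)
        est = weighted_mode(pairs, n_boot=20, seed=1)
        assert abs(est.beta) < 0.3

    def test_grid_argmax_matches_dense_grid_oracle(self, rng):
        from mrpath.mr_estimators import _mode_bandwidth

        bx = rng.uniform(0.05, 0.3, 6)
        by = rng.normal(0.03, 0.04, 6)
        sy = rng.uniform(0.01, 0.05, 6)
        est = weighted_mode(make_pairs(bx, by, sy), n_boot=10, seed=0)
        ratios = by / bx
        w = (np.abs(bx) / sy) ** 2
        w = w / w.sum()
        h = _mode_bandwidth(ratios, 1.0)
        dense = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20_001)
        dens = sum(
            w[i] * np.exp(-0.5 * ((dense - ratios[i]) / h) ** 2) for i in range(6)
        )
        assert est.beta == pytest.approx(dense[np.argmax(dens)], abs=2 * h * 6 / 511)

    def test_estimate_within_ratio_range(self, rng):
        bx = rng.uniform(0.05, 0.3, 6)
        by = rng.normal(0, 0.05, 6)
        est = weighted_mode(make_pairs(bx, by, 0.02), n_boot=10, seed=3)
        ratios = by / bx
        assert ratios.min() <= est.beta <= ratios.max()


class TestOddsRatioTransform:
    def test_null_effect_is_unit_or(self):
        est = ivw(make_pairs([0.2, 0.2], [0.0, 0.0], 0.02))
        orr, lo, hi = to_odds_ratio(est)
        assert orr == pytest.approx(1.0)
        assert lo < 1 < hi

    @pytest.mark.parametrize("target", [1.047, 0.917, 1.072, 1.230])
    def test_log_odds_round_trips_published_ors(self, target):
        est = ivw(make_pairs([1.0, 1.0], [np.log(target)] * 2, 0.02))
        orr, _, _ = to_odds_ratio(est)
        assert orr == pytest.approx(target, abs=5e-4)


@settings(derandomize=True, max_examples=30)
@given(scale=st.floats(0.1, 10), seed=st.integers(0, 10))
def test_outcome_scale_equivariance(scale, seed):
    """Multiplying all outcome betas and SEs by c>0 scales every estimator's
    beta and SE by c."""
    r = np.random.default_rng(seed)
    bx = r.uniform(0.05, 0.3, 6)
    by = 0.3 * bx + r.normal(0, 0.02, 6)
    sy = r.uniform(0.01, 0.05, 6)
    base = make_pairs(bx, by, sy)
    scaled = make_pairs(bx, by * scale, sy * scale)
    for fn in (
        lambda p: ivw(p, mode="fixed"),
        egger,
        lambda p: weighted_median(p, n_boot=30, seed=5),
        lambda p: weighted_mode(p, n_boot=30, seed=5),
    ):
        a, b = fn(base), fn(scaled)
        assert b.beta == pytest.approx(scale * a.beta, rel=1e-9)
        assert b.se == pytest.approx(scale * a.se, rel=1e-9)


def test_all_estimators_converge_to_true_slope_as_noise_vanishes(rng):
    """No pleiotropy, strong instruments: every estimator finds the slope."""
    bx = rng.uniform(0.1, 0.4, 12)
    by = 0.25 * bx + rng.normal(0, 1e-7, 12)
    pairs = make_pairs(bx, by, 1e-6, se_exp=1e-7)
    for est in (
        ivw(pairs),
        egger(pairs),
        weighted_median(pairs, n_boot=30, seed=1),
        weighted_mode(pairs, n_boot=30, seed=1),
    ):
        assert est.beta == pytest.approx(0.25, abs=1e-3)
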