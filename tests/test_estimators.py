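"""Estimator correctness against independent oracles (statsmodels WLS,
brute-force interpolation/grid search) and their documented invariants."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrpipe._errors import InsufficientInstrumentsError, ValidationError
from mrpipe.estimators import (
    BootstrapSpec, egger, ivw, mode_estimate, presso, wald_ratio, weighted_median,
)
from mrpipe.synthetic_data import SimConfig, simulate_harmonized
from conftest import hs_from_arrays, mk_h


def _random_hs(rng, J=6):
    bx = rng.uniform(0.1, 0.5, J) * rng.choice([-1, 1], J)
    by = 0.3 * bx + rng.normal(0, 0.02, J)
    sy = rng.uniform(0.01, 0.05, J)
    sx = rng.uniform(0.005, 0.02, J)
    return hs_from_arrays(bx, by, sy, sx)


class TestWaldRatio:
    def test_null_outcome_effect(self):
        est = wald_ratio(mk_h(0.1, 0.0, 0.02))
        assert est.theta == 0.0 and est.pval == 1.0

    def test_direct_formula(self):
        est = wald_ratio(mk_h(0.1, 0.05, 0.02))
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValidationError):
            wald_ratio(mk_h(0.0, 0.05, 0.02))

    def test_first_vs_second_order_delta_close_for_strong_instruments(self, rng):
        """For a strong instrument (se_x/|beta_x| < 0.1) with a modest
        outcome association (|beta_y| within 3 SE, the two-sample regime),
        the second-order delta SE differs from first-order by under 5%."""
        for _ in range(20):
            bx = rng.uniform(0.2, 0.6)
            sy = rng.uniform(0.01, 0.05)
            h = mk_h(bx, sy * rng.uniform(-3, 3), sy,
                     sx=rng.uniform(0.001, 0.099 * bx))
            first = wald_ratio(h).se
            second = wald_ratio(h, second_order=True).se
            assert abs(second - first) / first < 0.05


class TestIvw:
    def test_duplicated_instrument_reduces_to_wald(self):
        h = mk_h(0.2, 0.06, 0.02)
        J = 9
        est = ivw([mk_h(0.2, 0.06, 0.02, snp_id=f"rs{i}") for i in range(J)])
        wald = wald_ratio(h)
        assert est.theta == pytest.approx(wald.theta)
        # perfect agreement: residual scale floors at 1, so the fixed-effect
        # SE shrinks by sqrt(J)
        assert est.se == pytest.approx(wald.se / np.sqrt(J))

    def test_perfect_collinearity_floors_scale(self):
        bx = np.array([0.1, 0.2, 0.4])
        hs = hs_from_arrays(bx, 0.35 * bx, [0.02, 0.03, 0.01])
        est = ivw(hs)
        assert est.theta == pytest.approx(0.35, rel=1e-12)
        assert est.se == pytest.approx(np.sqrt(1.0 / np.sum(bx**2 / np.array([0.02, 0.03, 0.01]) ** 2)))

    def test_matches_wls_oracle(self, rng):
        """Three-instrument fixture: point estimate equals weighted least
        squares through the origin to 1e-12."""
        hs = _random_hs(rng, J=3)
        bx = np.array([h.beta_x for h in hs])
        by = np.array([h.beta_y for h in hs])
        w = np.array([1 / h.se_y**2 for h in hs])
        fit = sm.WLS(by, bx[:, None], weights=w).fit()
        assert ivw(hs).theta == pytest.approx(fit.params[0], abs=1e-12)

    def test_equals_weighted_mean_of_wald_ratios(self, rng):
        """Algebraic identity: IVW == mean of per-SNP ratios weighted by
        beta_x^2/se_y^2."""
        for _ in range(10):
            hs = _random_hs(rng, J=8)
            ratios = np.array([h.beta_y / h.beta_x for h in hs])
            w = np.array([h.beta_x**2 / h.se_y**2 for h in hs])
            assert ivw(hs).theta == pytest.approx(
                np.sum(w * ratios) / np.sum(w), abs=1e-12)

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([mk_h(0.2, 0.06, 0.02)])


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        hs = hs_from_arrays(bx, 0.02 + 0.4 * bx, [0.02, 0.01, 0.03, 0.02])
        result = egger(hs)
        assert result.slope.theta == pytest.approx(0.4, abs=1e-12)
        assert result.intercept.theta == pytest.approx(0.02, abs=1e-12)

    def test_matches_wls_oracle_and_hand_i2gx(self):
        bx = np.array([0.12, 0.25, 0.31, 0.48])
        by = np.array([0.03, 0.11, 0.09, 0.22])
        sy = np.array([0.02, 0.01, 0.03, 0.02])
        sx = np.array([0.01, 0.02, 0.01, 0.015])
        hs = hs_from_arrays(bx, by, sy, sx)
        result = egger(hs)

        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert result.intercept.theta == pytest.approx(fit.params[0], abs=1e-12)
        assert result.slope.theta == pytest.approx(fit.params[1], abs=1e-12)

        wx = 1 / sx**2
        xbar = np.sum(wx * bx) / np.sum(wx)
        q_gx = np.sum(wx * (bx - xbar) ** 2)
        assert result.i2gx == pytest.approx((q_gx - 3) / q_gx, abs=1e-12)

    def test_nome_limit(self):
        bx = np.array([0.1, 0.25, 0.4])
        hs = hs_from_arrays(bx, 0.3 * bx, [0.02] * 3, sx=[1e-8] * 3)
        result = egger(hs)
        assert result.i2gx == pytest.approx(1.0, abs=1e-6)
        assert not result.nome_warning

    def test_slope_with_zero_intercept_equals_ivw(self, rng):
        """Constraining the Egger intercept to zero recovers IVW exactly
        (checked by refitting the constrained model with an oracle)."""
        hs = _random_hs(rng, J=5)
        bx = np.abs([h.beta_x for h in hs])
        by = [np.sign(h.beta_x) * h.beta_y for h in hs]
        w = [1 / h.se_y**2 for h in hs]
        constrained = sm.WLS(by, np.asarray(bx)[:, None], weights=w).fit()
        assert ivw(hs).theta == pytest.approx(constrained.params[0], abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(hs_from_arrays([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))


def _brute_median(ratios, weights):
    """Independent cumulative-weight interpolation oracle."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2
    below = np.where(p <= 0.5)[0]
    above = np.where(p >= 0.5)[0]
    if len(below) == 0:
        return r[0]
    if len(above) == 0:
        return r[-1]
    i, j = below[-1], above[0]
    if i == j:
        return r[i]
    frac = (0.5 - p[i]) / (p[j] - p[i])
    return r[i] + frac * (r[j] - r[i])


class TestWeightedMedian:
    def test_middle_element_with_equal_weights(self):
        hs = hs_from_arrays([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.02] * 3)
        assert weighted_median(hs).theta == pytest.approx(0.2)

    def test_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        hs = hs_from_arrays(bx, 0.25 * bx, [0.02] * 3)
        est = weighted_median(hs, BootstrapSpec(500, seed=7))
        assert est.theta == pytest.approx(0.25)
        assert est.se < 0.25  # sampling-only spread, not degenerate

    def test_matches_interpolation_oracle(self, rng):
        for _ in range(20):
            hs = _random_hs(rng, J=5)
            ratios = [h.beta_y / h.beta_x for h in hs]
            weights = [h.beta_x**2 / h.se_y**2 for h in hs]
            assert weighted_median(hs).theta == pytest.approx(
                _brute_median(ratios, weights), abs=1e-12)

    def test_bootstrap_se_stable_across_seeds(self, rng):
        hs = _random_hs(rng, J=5)
        se1 = weighted_median(hs, BootstrapSpec(5000, seed=1)).se
        se2 = weighted_median(hs, BootstrapSpec(5000, seed=2)).se
        assert abs(se1 - se2) / se1 < 0.05

    def test_bootstrap_spec_floor(self):
        with pytest.raises(ValidationError):
            BootstrapSpec(50, seed=1)


class TestModeEstimate:
    def test_point_mass(self):
        bx = np.array([0.1, 0.2, 0.3])
        hs = hs_from_arrays(bx, 0.4 * bx, [0.02] * 3)
        assert mode_estimate(hs, weighted=False).theta == pytest.approx(0.4)

    def test_majority_cluster_beats_outlier(self):
        hs = hs_from_arrays([0.2, 0.25, 0.3, 0.1],
                            [0.1, 0.126, 0.149, 0.5],
                            [0.02, 0.02, 0.02, 0.02])
        est = mode_estimate(hs, weighted=False)
        assert est.theta == pytest.approx(0.5, abs=0.1)  # cluster near 0.5

    def test_weighted_mode_matches_grid_oracle(self, rng):
        """Two-cluster fixture: the weighted mode picks the heavy cluster and
        agrees with a dense grid argmax of the same kernel density."""
        ratios = np.array([0.1, 0.12, 0.11, 0.5, 0.52])
        weights = np.array([5.0, 5.0, 5.0, 1.0, 1.0])
        bx = np.sqrt(weights) * 0.02 * 10  # so that bx^2/se_y^2 == weights
        sy = np.full(5, 0.2)
        hs = hs_from_arrays(bx, ratios * bx, sy)
        est = mode_estimate(hs, weighted=True)

        sd = np.std(ratios, ddof=1)
        mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
        h = 0.9 * min(sd, mad) * 5 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200_001)
        dens = sum(w * np.exp(-0.5 * ((grid - r) / h) ** 2)
                   for r, w in zip(ratios, weights))
        oracle = grid[np.argmax(dens)]
        assert abs(est.theta - oracle) < 1e-3
        assert abs(est.theta - 0.11) < 0.05  # heavy cluster wins

    def test_bandwidth_factor_must_be_positive(self):
        hs = hs_from_arrays([0.1, 0.2, 0.3], [0.05, 0.1, 0.2], [0.02] * 3)
        with pytest.raises(ValidationError):
            mode_estimate(hs, bandwidth_factor=0.0)


class TestPresso:
    def _clean(self, rng, J=8):
        bx = rng.uniform(0.1, 0.5, J)
        sy = np.full(J, 0.02)
        by = 0.3 * bx + rng.normal(0, 0.002, J)
        return hs_from_arrays(bx, by, sy, sx=np.full(J, 0.001))

    def test_clean_data_large_global_p_no_outliers(self, rng):
        result = presso(self._clean(rng), n_sim=500, seed=5)
        assert result.global_p > 0.05
        assert result.outlier_indices == []
        assert result.corrected is None

    def test_planted_outlier_flagged_and_corrected(self, rng):
        hs = self._clean(rng, J=14)
        hs.append(mk_h(0.3, 0.3 * 0.3 + 10 * 0.02, 0.02, sx=0.001, snp_id="rs15"))
        result = presso(hs, n_sim=1000, seed=11)
        assert 14 in result.outlier_indices
        assert result.outlier_pvals[14] < 0.05
        assert result.global_p < 0.05
        # corrected estimate == IVW on the retained subset, exactly
        retained = [h for i, h in enumerate(hs) if i not in result.outlier_indices]
        assert result.corrected.theta == ivw(retained).theta
        assert result.distortion_p is not None

    def test_requires_four_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            presso(hs_from_arrays([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], [0.02] * 3))


class TestOrderInvariance:
    def test_all_estimators_invariant_to_instrument_order(self, rng):
        hs = _random_hs(rng, J=7)
        perm = list(rng.permutation(7))
        shuffled = [hs[i] for i in perm]
        assert ivw(hs).theta == pytest.approx(ivw(shuffled).theta, abs=1e-12)
        assert egger(hs).slope.theta == pytest.approx(
            egger(shuffled).slope.theta, abs=1e-12)
        assert weighted_median(hs).theta == pytest.approx(
            weighted_median(shuffled).theta, abs=1e-12)
        assert mode_estimate(hs).theta == pytest.approx(
            mode_estimate(shuffled).theta, abs=1e-10)


class TestRecoveryOnSyntheticData:
    def test_single_instrument_wald_coverage(self):
        """J = 1 routes to the Wald ratio; the truth lies within 2 SE in at
        least 93% of replicates (the single-SNP exposure situation)."""
        cfg = SimConfig(theta=0.4, j_instruments=1)
        rng = np.random.default_rng(77)
        hits = 0
        R = 400
        for _ in range(R):
            hs, truth = simulate_harmonized(cfg, rng)
            est = wald_ratio(hs[0])
            hits += abs(est.theta - 0.4) <= 2 * est.se
        assert hits / R >= 0.93

    def test_weighted_median_robust_where_ivw_biased(self):
        """With 40% of weight on directionally pleiotropic instruments and a
        large outcome study, the weighted median stays near the truth while
        IVW drifts (the sanity contrast)."""
        cfg = SimConfig(theta=0.2, j_instruments=50, pleiotropy_mean=0.05,
                        pleiotropy_frac=0.4, n_outcome=1_600_000)
        rng = np.random.default_rng(88)
        wm, iv = [], []
        for _ in range(150):
            hs, _ = simulate_harmonized(cfg, rng)
            wm.append(weighted_median(hs).theta)
            iv.append(ivw(hs).theta)
        assert abs(np.mean(wm) - 0.2) < 0.02
        assert abs(np.mean(iv) - 0.2) > 0.03
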