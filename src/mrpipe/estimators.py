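"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized per-SNP effect pairs (β̂_Xj, β̂_Yj) with
standard errors (σ_Xj, σ_Yj) and estimate the causal effect θ in the model

    β_Yj = θ·β_Xj + α_j,

where α_j is the direct (pleiotropic) effect of instrument j on the outcome.

* Wald ratio: θ̂_j = β̂_Yj/β̂_Xj, the single-instrument estimate.
* IVW: inverse-variance-weighted regression of β̂_Y on β̂_X through the
  origin (unbiased when pleiotropy is absent or balanced); multiplicative
  random effects inflate the SE by the residual scale, floored at 1.
* MR-Egger: the same regression with a free intercept; the intercept
  estimates directional pleiotropy (valid under InSIDE), and the I²_GX
  statistic quantifies violation of the no-measurement-error assumption.
* Weighted median: consistent when ≥50% of the weight lies on valid
  instruments.
* Simple/weighted mode: the kernel-density mode of the per-SNP ratios,
  consistent when the largest group of instruments is valid (ZEMPA).
* MR-PRESSO: simulation-based residual-sum-of-squares test that detects
  global pleiotropy, flags outlier instruments, and re-estimates without
  them.

Bootstrap and simulation procedures take explicit seeds and are reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2, norm

from ._errors import InsufficientInstrumentsError, ValidationError
from .harmonize import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "BootstrapSpec",
    "EggerResult",
    "PressoResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "presso",
]


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    theta: float
    se: float
    pval: float
    n_snp: int
    weights: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass
class BootstrapSpec:
    """Parametric-bootstrap settings for median/mode standard errors."""

    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 100:
            raise ValidationError("n_draws must be >= 100 for reported SEs")


@dataclass
class EggerResult:
    """MR-Egger slope, intercept, and the NOME diagnostic I²_GX."""

    slope: MREstimate
    intercept: MREstimate
    i2gx: float
    nome_warning: bool


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion test results."""

    global_p: float
    global_rss: float
    outlier_pvals: np.ndarray  # Bonferroni-adjusted, one per instrument
    outlier_indices: list[int]
    raw: MREstimate
    corrected: Optional[MREstimate]
    distortion_p: Optional[float]


def _arrays(hs: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_x for h in hs], dtype=float)
    sx = np.array([h.se_x for h in hs], dtype=float)
    by = np.array([h.beta_y for h in hs], dtype=float)
    sy = np.array([h.se_y for h in hs], dtype=float)
    return bx, sx, by, sy


def _normal_p(theta: float, se: float) -> float:
    if se == 0.0:
        return 1.0 if theta == 0.0 else 0.0
    return float(2.0 * norm.sf(abs(theta) / se))


def wald_ratio(h: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-instrument ratio estimate θ̂ = β̂_Y/β̂_X.

    The default SE is the first-order delta approximation σ_Y/|β̂_X|;
    ``second_order=True`` adds the exposure-uncertainty term
    sqrt(σ_Y²/β̂_X² + β̂_Y²σ_X²/β̂_X⁴).
    """
    if h.beta_x == 0.0:
        raise ValidationError(f"{h.snp_id}: Wald ratio undefined for beta_x = 0")
    theta = h.beta_y / h.beta_x
    if second_order:
        se = float(
            np.sqrt(h.se_y**2 / h.beta_x**2 + h.beta_y**2 * h.se_x**2 / h.beta_x**4)
        )
    else:
        se = h.se_y / abs(h.beta_x)
    return MREstimate("wald", float(theta), float(se), _normal_p(theta, se), 1)


def ivw(hs: Sequence[HarmonizedInstrument]) -> MREstimate:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    Weighted regression of β̂_Y on β̂_X through the origin with weights
    w_j = 1/σ_Yj²; algebraically identical to the w_j·β̂_Xj²-weighted mean of
    the per-SNP Wald ratios.  The SE is sqrt(1/Σ w_j β̂_Xj²) scaled by the
    residual standard deviation when it exceeds 1 (over-dispersion), and
    unscaled otherwise (fixed effect).
    """
    if len(hs) < 2:
        raise InsufficientInstrumentsError("ivw requires >= 2 instruments; use wald_ratio")
    bx, _, by, sy = _arrays(hs)
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by) / sxx)
    resid = by - theta * bx
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss / (len(hs) - 1)))
    se = float(np.sqrt(1.0 / sxx) * scale)
    return MREstimate("ivw", theta, se, _normal_p(theta, se), len(hs), weights=w)


def egger(hs: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger regression with the I²_GX NOME diagnostic.

    Instruments are first oriented so every β̂_X ≥ 0 (the intercept is only
    interpretable under a fixed exposure-increasing allele convention); then
    β̂_Y is regressed on β̂_X with a free intercept and weights 1/σ_Y².
    I²_GX = (Q_GX − (J−1))/Q_GX, with Q_GX the weighted dispersion of the
    β̂_X, measures attenuation from exposure-side measurement error; values
    below 0.9 flag a NOME violation.
    """
    J = len(hs)
    if J < 3:
        raise InsufficientInstrumentsError("egger requires >= 3 instruments")
    bx, sx, by, sy = _arrays(hs)
    orient = np.where(bx < 0.0, -1.0, 1.0)
    bx = bx * orient
    by = by * orient
    w = 1.0 / sy**2

    sw = float(np.sum(w))
    sx_w = float(np.sum(w * bx))
    sy_w = float(np.sum(w * by))
    sxx = float(np.sum(w * bx**2))
    sxy = float(np.sum(w * bx * by))
    den = sw * sxx - sx_w**2
    if den <= 0.0:
        raise ValidationError("egger: degenerate design (no spread in beta_x)")
    slope = (sw * sxy - sx_w * sy_w) / den
    intercept = (sxx * sy_w - sx_w * sxy) / den

    resid = by - intercept - slope * bx
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss / (J - 2))) if J > 2 else 1.0
    se_slope = float(np.sqrt(sw / den) * scale)
    se_intercept = float(np.sqrt(sxx / den) * scale)

    wx = 1.0 / sx**2
    bx_wbar = float(np.sum(wx * bx) / np.sum(wx))
    q_gx = float(np.sum((bx - bx_wbar) ** 2 * wx))
    i2gx = max(0.0, (q_gx - (J - 1)) / q_gx) if q_gx > 0.0 else 0.0

    return EggerResult(
        slope=MREstimate("egger_slope", float(slope), se_slope,
                         _normal_p(slope, se_slope), J, weights=w),
        intercept=MREstimate("egger_intercept", float(intercept), se_intercept,
                             _normal_p(intercept, se_intercept), J),
        i2gx=i2gx,
        nome_warning=i2gx < 0.9,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with midpoint cumulative-weight interpolation."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w)
    p = cum - w / 2.0  # midpoint convention
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(
    hs: Sequence[HarmonizedInstrument],
    boot: Optional[BootstrapSpec] = None,
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Per-SNP Wald ratios are ordered and the ratio at cumulative normalized
    weight 0.5 (weights β̂_X²/σ_Y², midpoint convention, linear interpolation)
    is the estimate.  The SE is the standard deviation of the estimate over
    parametric redraws β̂* ~ N(β̂, σ); ``boot=None`` returns the point
    estimate only (se and p reported as NaN).
    """
    if len(hs) < 3:
        raise InsufficientInstrumentsError("weighted_median requires >= 3 instruments")
    bx, sx, by, sy = _arrays(hs)
    ratios = by / bx
    weights = bx**2 / sy**2
    theta = _weighted_median_point(ratios, weights)
    if boot is None:
        return MREstimate("weighted_median", theta, float("nan"), float("nan"),
                          len(hs), weights=weights)
    rng = np.random.default_rng(boot.seed)
    bx_star = rng.normal(bx, sx, size=(boot.n_draws, len(hs)))
    by_star = rng.normal(by, sy, size=(boot.n_draws, len(hs)))
    draws = np.empty(boot.n_draws)
    for i in range(boot.n_draws):
        draws[i] = _weighted_median_point(
            by_star[i] / bx_star[i], bx_star[i] ** 2 / sy**2
        )
    se = float(np.std(draws, ddof=1))
    return MREstimate("weighted_median", theta, se, _normal_p(theta, se),
                      len(hs), weights=weights)


def _mode_point(ratios: np.ndarray, weights: np.ndarray,
                bandwidth_factor: float, grid_size: int = 2048) -> float:
    """Argmax of the weighted Gaussian-kernel density of the ratios.

    Bandwidth follows the modified Silverman rule
    h = φ · 0.9 · min(sd, MAD) · J^{-1/5} with MAD scaled for normal
    consistency (×1.4826).
    """
    if np.allclose(ratios, ratios[0]):
        return float(ratios[0])
    sd = float(np.std(ratios, ddof=1))
    mad = float(1.4826 * np.median(np.abs(ratios - np.median(ratios))))
    spread = min(x for x in (sd, mad) if x > 0.0)
    h = bandwidth_factor * 0.9 * spread * len(ratios) ** (-1.0 / 5.0)
    grid = np.linspace(ratios.min() - 3.0 * h, ratios.max() + 3.0 * h, grid_size)
    density = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[int(np.argmax(density))])


def mode_estimate(
    hs: Sequence[HarmonizedInstrument],
    weighted: bool = True,
    boot: Optional[BootstrapSpec] = None,
    bandwidth_factor: float = 1.0,
) -> MREstimate:
    """Mode-based estimate (simple or inverse-variance-weighted).

    The estimate is the mode of the kernel-smoothed density of per-SNP Wald
    ratios; it is consistent when the largest homogeneous cluster of
    instruments is valid, even if they carry under half the weight.
    """
    if len(hs) < 3:
        raise InsufficientInstrumentsError("mode_estimate requires >= 3 instruments")
    if bandwidth_factor <= 0.0:
        raise ValidationError("bandwidth_factor must be positive")
    bx, sx, by, sy = _arrays(hs)
    ratios = by / bx
    weights = bx**2 / sy**2 if weighted else np.ones_like(ratios)
    theta = _mode_point(ratios, weights, bandwidth_factor)
    method = "weighted_mode" if weighted else "simple_mode"
    if boot is None:
        return MREstimate(method, theta, float("nan"), float("nan"),
                          len(hs), weights=weights)
    rng = np.random.default_rng(boot.seed)
    bx_star = rng.normal(bx, sx, size=(boot.n_draws, len(hs)))
    by_star = rng.normal(by, sy, size=(boot.n_draws, len(hs)))
    draws = np.empty(boot.n_draws)
    for i in range(boot.n_draws):
        r_star = by_star[i] / bx_star[i]
        w_star = bx_star[i] ** 2 / sy**2 if weighted else weights
        draws[i] = _mode_point(r_star, w_star, bandwidth_factor, grid_size=512)
    se = float(np.std(draws, ddof=1))
    return MREstimate(method, theta, se, _normal_p(theta, se), len(hs), weights=weights)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW (fixed-effect) slopes, one per left-out instrument."""
    sxx = np.sum(w * bx**2)
    sxy = np.sum(w * bx * by)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def presso(
    hs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier test.

    The observed statistic is the weighted RSS of each instrument against its
    leave-one-out IVW prediction.  The null distribution is built by
    simulating (β̂_X*, β̂_Y*) from their standard errors around the
    leave-one-out fits ``n_sim`` times and recomputing the statistic (with
    leave-one-out slopes re-estimated per simulation).  The global p is the
    null exceedance fraction with a +1/(n_sim+1) continuity correction;
    per-SNP outlier p-values come from each SNP's simulated squared-residual
    distribution, Bonferroni-adjusted over J.  When outliers are found, the
    corrected estimate is IVW on the retained instruments and the distortion
    p compares the raw-minus-corrected shift against removal of random
    subsets of the same size.
    """
    J = len(hs)
    if J < 4:
        raise InsufficientInstrumentsError("presso requires >= 4 instruments")
    if n_sim < 100:
        raise ValidationError("n_sim must be >= 100")
    bx, sx, by, sy = _arrays(hs)
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    resid_obs = by - theta_loo * bx
    rss_j_obs = w * resid_obs**2
    rss_obs = float(np.sum(rss_j_obs))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, J))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    sxx_star = np.sum(w * bx_star**2, axis=1, keepdims=True)
    sxy_star = np.sum(w * bx_star * by_star, axis=1, keepdims=True)
    theta_loo_star = (sxy_star - w * bx_star * by_star) / (sxx_star - w * bx_star**2)
    resid_star = by_star - theta_loo_star * bx_star
    rss_j_star = w * resid_star**2
    rss_star = np.sum(rss_j_star, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(rss_j_star >= rss_j_obs, axis=0)) / (n_sim + 1)
    outlier_pvals = np.minimum(1.0, per_snp_p * J)
    outlier_indices = [int(i) for i in np.flatnonzero(outlier_pvals < outlier_alpha)]

    raw = ivw(hs)
    corrected = None
    distortion_p = None
    if outlier_indices and J - len(outlier_indices) >= 2:
        retained = [h for i, h in enumerate(hs) if i not in outlier_indices]
        corrected = ivw(retained)
        d_obs = raw.theta - corrected.theta
        k = len(outlier_indices)
        d_null = np.empty(n_sim)
        all_idx = np.arange(J)
        for s in range(n_sim):
            removed = rng.choice(all_idx, size=k, replace=False)
            keep = np.setdiff1d(all_idx, removed, assume_unique=True)
            theta_sub = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(
                w[keep] * bx[keep] ** 2
            )
            d_null[s] = raw.theta - theta_sub
        distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))

    return PressoResult(
        global_p=global_p,
        global_rss=rss_obs,
        outlier_pvals=outlier_pvals,
        outlier_indices=outlier_indices,
        raw=raw,
        corrected=corrected,
        distortion_p=distortion_p,
    )
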