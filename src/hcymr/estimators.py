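"""Core two-sample MR estimators.

Given J harmonized instruments with exposure effects beta_X (SE se_X) and
outcome effects beta_Y (SE se_Y), each SNP's Wald ratio

    theta_j = beta_Y_j / beta_X_j,   se(theta_j) ~= se_Y_j / |beta_X_j|

is an estimate of the causal effect of the exposure on the outcome (log
odds ratio per unit exposure for a binary outcome).  The estimators here
combine the ratios under progressively weaker validity assumptions:

* ``ivw`` — inverse-variance weighted mean of the Wald ratios, equivalent
  to weighted least squares of beta_Y on beta_X through the origin with
  weights 1/se_Y^2.  Unbiased when all instruments are valid.  The
  multiplicative random-effects variant inflates the SE by
  max(1, sqrt(Q/(J-1))) when heterogeneity exceeds its expectation.
* ``weighted_median`` — consistent when instruments carrying at least half
  of the total weight are valid; SE from a parametric bootstrap.
* ``mr_egger`` — weighted regression of beta_Y on beta_X with a free
  intercept; the intercept estimates the average directional (horizontal)
  pleiotropy per SNP and its Wald test is the pleiotropy diagnostic, while
  the slope remains a consistent causal estimate under the InSIDE
  assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_data import (
    EffectWithCI,
    HarmonizedDataset,
    ValidationError,
    to_effect_with_ci,
)

log = logging.getLogger(__name__)

IVW_MODELS = ("fixed", "multiplicative_random")


@dataclass(frozen=True)
class WaldRatioSet:
    """Per-SNP causal-effect ratios and their inverse-variance weights."""

    snps: list[str]
    ratio: np.ndarray
    se_ratio: np.ndarray
    weight: np.ndarray


def wald_ratios(ds: HarmonizedDataset) -> WaldRatioSet:
    """Per-SNP Wald ratios with first-order delta-method standard errors.

    theta_j = bY_j / bX_j; se_j = seY_j / |bX_j|; weight_j = 1/se_j^2
    = bX_j^2 / seY_j^2.  A zero exposure effect has no defined ratio and is
    rejected by name.
    """
    zero = [s for s, b in zip(ds.snps, ds.beta_exposure) if b == 0.0]
    if zero:
        raise ZeroDivisionError(
            f"beta_exposure is exactly 0 for {', '.join(zero)}; Wald ratio undefined"
        )
    ratio = ds.beta_outcome / ds.beta_exposure
    se_ratio = ds.se_outcome / np.abs(ds.beta_exposure)
    weight = ds.beta_exposure**2 / ds.se_outcome**2
    return WaldRatioSet(snps=list(ds.snps), ratio=ratio, se_ratio=se_ratio, weight=weight)


def cochran_q(ds: HarmonizedDataset) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic about the fixed-effect IVW mean,
    with its chi-square(J-1) p-value."""
    wr = wald_ratios(ds)
    est = float(np.sum(wr.weight * wr.ratio) / np.sum(wr.weight))
    q = float(np.sum(wr.weight * (wr.ratio - est) ** 2))
    return q, float(stats.chi2.sf(q, ds.n_snps - 1))


def ivw(
    ds: HarmonizedDataset,
    model: str = "multiplicative_random",
    alpha: float = 0.05,
) -> EffectWithCI:
    """Inverse-variance weighted estimate over the instrument set.

    ``model="fixed"`` uses se = 1/sqrt(sum of weights); the default
    ``"multiplicative_random"`` scales that SE by max(1, sqrt(Q/(J-1)))
    where Q is Cochran's heterogeneity statistic, so under-dispersed data
    fall back to the fixed-effect SE and over-dispersed data get a wider
    interval.  With a single instrument the estimate is that SNP's Wald
    ratio and the model silently degrades to fixed.
    """
    if model not in IVW_MODELS:
        raise ValidationError(f"unknown IVW model {model!r}; expected one of {IVW_MODELS}")
    wr = wald_ratios(ds)
    j = ds.n_snps
    sum_w = float(np.sum(wr.weight))
    estimate = float(np.sum(wr.weight * wr.ratio) / sum_w)
    se = 1.0 / np.sqrt(sum_w)
    label = "IVW-fixed"
    if model == "multiplicative_random":
        if j >= 2:
            q = float(np.sum(wr.weight * (wr.ratio - estimate) ** 2))
            se *= max(1.0, np.sqrt(q / (j - 1)))
            label = "IVW-mre"
        else:
            log.warning("single instrument: multiplicative_random falls back to fixed")
            label = "IVW-fixed"
    return to_effect_with_ci(estimate, se, j, label, alpha=alpha)


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Midpoint-convention weighted median of ratios.

    Order the ratios, normalize the weights, and set s_j = (cumulative sum
    through j) - w_j/2; the estimate interpolates theta linearly across s at
    the 50% point.  With all mass on one ratio this returns that ratio.
    """
    order = np.argsort(ratio, kind="stable")
    th = ratio[order]
    w = weight[order] / np.sum(weight)
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(th[0])
    if 0.5 >= s[-1]:
        return float(th[-1])
    return float(np.interp(0.5, s, th))


def weighted_median(
    ds: HarmonizedDataset,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> EffectWithCI:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate is the inverse-variance weighted median of the Wald
    ratios.  The SE is the standard deviation of the estimate across
    ``n_boot`` parametric resamples beta_X* ~ N(beta_X, se_X),
    beta_Y* ~ N(beta_Y, se_Y); a seed makes the bootstrap reproducible.
    """
    if ds.n_snps < 3:
        raise ValidationError("weighted median requires at least 3 instruments")
    if n_boot < 2:
        raise ValidationError("n_boot must be at least 2")
    wr = wald_ratios(ds)
    estimate = _weighted_median_point(wr.ratio, wr.weight)

    rng = np.random.default_rng(seed)
    j = ds.n_snps
    bx = rng.normal(ds.beta_exposure, ds.se_exposure, size=(n_boot, j))
    by = rng.normal(ds.beta_outcome, ds.se_outcome, size=(n_boot, j))
    bx[bx == 0.0] = np.finfo(float).tiny  # guard: resampled exposure effect of exactly 0
    reps = np.empty(n_boot)
    for b in range(n_boot):
        ratio = by[b] / bx[b]
        weight = bx[b] ** 2 / ds.se_outcome**2
        reps[b] = _weighted_median_point(ratio, weight)
    se = float(np.std(reps, ddof=1))
    if se == 0.0:
        se = np.finfo(float).tiny
    return to_effect_with_ci(estimate, se, j, "weighted-median", alpha=alpha)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger regression fit: causal slope plus pleiotropy intercept test."""

    slope: float
    se_slope: float
    intercept: float
    se_intercept: float
    intercept_pvalue: float
    n_snps: int
    dispersion: float

    def slope_effect(self, alpha: float = 0.05) -> EffectWithCI:
        return to_effect_with_ci(self.slope, self.se_slope, self.n_snps, "MR-Egger", alpha=alpha)


def mr_egger(ds: HarmonizedDataset) -> EggerResult:
    """Weighted regression of outcome on exposure effects with free intercept.

    Instruments are first oriented so every exposure effect is positive
    (negating both betas of a SNP leaves its Wald ratio unchanged but makes
    the intercept identifiable).  The fit is WLS with weights 1/se_Y^2; SEs
    carry a multiplicative dispersion factor max(1, sqrt(RSS/(J-2))), and
    the intercept p-value is the two-sided normal tail.
    """
    if ds.n_snps < 3:
        raise ValidationError("MR-Egger requires at least 3 instruments")
    sign = np.where(ds.beta_exposure < 0, -1.0, 1.0)
    x = ds.beta_exposure * sign
    y = ds.beta_outcome * sign
    w = 1.0 / ds.se_outcome**2
    if np.ptp(x) == 0.0:
        raise ValidationError("all exposure effects identical after orientation; no leverage")

    # 2-parameter weighted normal equations; dispersion handled explicitly
    sw, swx, swx2 = np.sum(w), np.sum(w * x), np.sum(w * x * x)
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    det = sw * swx2 - swx**2
    intercept = (swx2 * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    j = ds.n_snps
    dispersion = max(1.0, np.sqrt(rss / (j - 2)))
    var_intercept = swx2 / det * dispersion**2
    var_slope = sw / det * dispersion**2
    se_intercept = float(np.sqrt(var_intercept))
    se_slope = float(np.sqrt(var_slope))
    p_int = float(2.0 * stats.norm.sf(abs(intercept / se_intercept)))
    return EggerResult(
        slope=float(slope),
        se_slope=se_slope,
        intercept=float(intercept),
        se_intercept=se_intercept,
        intercept_pvalue=min(p_int, 1.0) if p_int > 0 else 5e-324,
        n_snps=j,
        dispersion=float(dispersion),
    )
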