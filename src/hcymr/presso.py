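"""MR-PRESSO style outlier diagnostics for two-sample MR.

Three linked resampling tests built on leave-one-out weighted residuals:

* **global test** — is the observed residual sum of squares (RSS) larger
  than expected under the model beta_Y = theta * beta_X with the stated
  outcome SEs?  Empirical p from simulated datasets.
* **outlier test** — which individual SNPs contribute an implausibly large
  weighted residual?  Per-SNP empirical p against each SNP's simulated
  residual distribution, Bonferroni-corrected across instruments.
* **distortion test** — does removing the flagged outliers move the causal
  estimate more than removing a random same-size subset would?

Residuals use the leave-one-out IVW estimate so a gross outlier cannot
mask itself by dragging the pooled estimate toward its own ratio.  The
weighted-residual convention is r_j^2 / se_Y_j^2 throughout.  All
simulation draws come from a single seeded generator, so results are
bit-reproducible.  By default only outcome-side noise is simulated;
``simulate_exposure_noise=True`` also perturbs the exposure betas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import ivw
from .summary_data import EffectWithCI, HarmonizedDataset, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PressoResult:
    """Output of the global / outlier / distortion test sequence."""

    rss_observed: float
    global_pvalue: float
    n_sim: int
    seed: int | None
    snps: list[str] = field(default_factory=list)
    snp_pvalues: dict[str, float] = field(default_factory=dict)
    outliers: list[str] = field(default_factory=list)
    corrected: EffectWithCI | None = None
    distortion_statistic: float | None = None
    distortion_pvalue: float | None = None
    too_few_remaining: bool = False


def _loo_estimates(beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimate for each SNP, vectorized."""
    w = beta_x**2 / se_y**2
    theta = beta_y / beta_x
    sw, swt = np.sum(w), np.sum(w * theta)
    return (swt - w * theta) / (sw - w)


def _weighted_residuals_sq(
    beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> np.ndarray:
    loo = _loo_estimates(beta_x, beta_y, se_y)
    r = beta_y - loo * beta_x
    return r**2 / se_y**2


def _simulated_residuals(
    ds: HarmonizedDataset,
    n_sim: int,
    rng: np.random.Generator,
    simulate_exposure_noise: bool,
) -> np.ndarray:
    """(n_sim, J) matrix of simulated per-SNP weighted squared residuals.

    Expected outcome betas are the leave-one-out predictions theta_-j * bX_j;
    each simulated dataset is re-analysed exactly like the observed one
    (its own LOO estimates), so the null distribution reflects estimation
    noise in the pooled ratio as well.
    """
    j = ds.n_snps
    loo = _loo_estimates(ds.beta_exposure, ds.beta_outcome, ds.se_outcome)
    if simulate_exposure_noise:
        bx = rng.normal(ds.beta_exposure, ds.se_exposure, size=(n_sim, j))
        bx[bx == 0.0] = np.finfo(float).tiny
    else:
        bx = np.broadcast_to(ds.beta_exposure, (n_sim, j))
    by = rng.normal(loo * ds.beta_exposure, ds.se_outcome, size=(n_sim, j))

    w = bx**2 / ds.se_outcome**2
    theta = by / bx
    sw = np.sum(w, axis=1, keepdims=True)
    swt = np.sum(w * theta, axis=1, keepdims=True)
    loo_sim = (swt - w * theta) / (sw - w)
    r = by - loo_sim * bx
    return r**2 / ds.se_outcome**2


def _empirical_p(count_ge: int, n_sim: int) -> float:
    # (count + 1) / (n_sim + 1): an empirical p is never exactly 0
    return (count_ge + 1) / (n_sim + 1)


def presso_global(
    ds: HarmonizedDataset,
    n_sim: int = 1000,
    seed: int | None = None,
    simulate_exposure_noise: bool = False,
) -> PressoResult:
    """Global heterogeneity test: empirical p for the observed total RSS."""
    _check_args(ds, n_sim)
    rng = np.random.default_rng(seed)
    obs = _weighted_residuals_sq(ds.beta_exposure, ds.beta_outcome, ds.se_outcome)
    rss_obs = float(np.sum(obs))
    sim = _simulated_residuals(ds, n_sim, rng, simulate_exposure_noise)
    rss_sim = np.sum(sim, axis=1)
    p = _empirical_p(int(np.sum(rss_sim >= rss_obs)), n_sim)
    return PressoResult(
        rss_observed=rss_obs,
        global_pvalue=p,
        n_sim=n_sim,
        seed=seed,
        snps=list(ds.snps),
    )


def presso_outlier(
    ds: HarmonizedDataset,
    n_sim: int = 1000,
    seed: int | None = None,
    sig_threshold: float = 0.05,
    simulate_exposure_noise: bool = False,
) -> PressoResult:
    """Global test plus per-SNP outlier test and outlier-corrected estimate.

    Each SNP's observed weighted squared residual is compared with its own
    simulated distribution; SNPs with Bonferroni-corrected empirical p
    below ``sig_threshold`` are flagged.  The corrected estimate is IVW on
    the non-flagged SNPs when at least 3 remain.
    """
    _check_args(ds, n_sim)
    rng = np.random.default_rng(seed)
    obs = _weighted_residuals_sq(ds.beta_exposure, ds.beta_outcome, ds.se_outcome)
    rss_obs = float(np.sum(obs))
    sim = _simulated_residuals(ds, n_sim, rng, simulate_exposure_noise)
    rss_sim = np.sum(sim, axis=1)
    global_p = _empirical_p(int(np.sum(rss_sim >= rss_obs)), n_sim)

    j = ds.n_snps
    counts = np.sum(sim >= obs[np.newaxis, :], axis=0)
    snp_p = {s: _empirical_p(int(c), n_sim) for s, c in zip(ds.snps, counts)}
    cutoff = sig_threshold / j  # Bonferroni across instruments
    outliers = [s for s in ds.snps if snp_p[s] < cutoff]

    result = PressoResult(
        rss_observed=rss_obs,
        global_pvalue=global_p,
        n_sim=n_sim,
        seed=seed,
        snps=list(ds.snps),
        snp_pvalues=snp_p,
        outliers=outliers,
    )
    if outliers:
        keep = [s for s in ds.snps if s not in outliers]
        if len(keep) >= 3:
            result.corrected = ivw(ds.subset(keep), model="fixed")
            stat, dist_p = presso_distortion(ds, outliers, n_sim=n_sim, seed=seed)
            result.distortion_statistic = stat
            result.distortion_pvalue = dist_p
        else:
            result.too_few_remaining = True
            log.warning(
                "outlier test flagged %d of %d SNPs; too few remain for a corrected estimate",
                len(outliers),
                j,
            )
    return result


def presso_distortion(
    ds: HarmonizedDataset,
    outliers: list[str],
    n_sim: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Distortion test for a given outlier set.

    The statistic is the relative shift (theta_corrected - theta_all) /
    |theta_all| of the fixed-effect IVW estimate.  Its empirical p compares
    the observed |shift| with shifts from ``n_sim`` random same-size
    subsets, answering whether the flagged SNPs distort the estimate more
    than arbitrary SNPs would.
    """
    outliers = list(outliers)
    if not outliers:
        raise ValidationError("distortion test requires a nonempty outlier set")
    missing = set(outliers) - set(ds.snps)
    if missing:
        raise ValidationError(f"outliers not in dataset: {', '.join(sorted(missing))}")
    keep = [s for s in ds.snps if s not in outliers]
    if len(keep) < 3:
        raise ValidationError("outlier removal must leave at least 3 SNPs")
    rng = np.random.default_rng(seed)

    theta_all = ivw(ds, model="fixed").estimate_log
    theta_corr = ivw(ds.subset(keep), model="fixed").estimate_log
    if theta_all == 0.0:
        stat = 0.0 if theta_corr == theta_all else np.inf
    else:
        stat = (theta_corr - theta_all) / abs(theta_all)

    k = len(outliers)
    snps = np.array(ds.snps)
    shifts = np.empty(n_sim)
    for i in range(n_sim):
        drop = rng.choice(snps, size=k, replace=False)
        sub = ds.subset([s for s in ds.snps if s not in set(drop)])
        t = ivw(sub, model="fixed").estimate_log
        shifts[i] = (t - theta_all) / abs(theta_all) if theta_all != 0.0 else 0.0
    p = _empirical_p(int(np.sum(np.abs(shifts) >= abs(stat))), n_sim)
    return float(stat), float(p)


def _check_args(ds: HarmonizedDataset, n_sim: int) -> None:
    if ds.n_snps < 4:
        raise ValidationError("MR-PRESSO requires at least 4 instruments")
    if n_sim < 10:
        raise ValidationError("n_sim must be at least 10")
    if n_sim < 100:
        log.warning("n_sim=%d is small; empirical p-values will be coarse", n_sim)
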