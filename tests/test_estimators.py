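"""Wald-ratio, IVW, weighted-median and MR-Egger estimators."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from hcymr.estimators import (
    _weighted_median_point,
    cochran_q,
    ivw,
    mr_egger,
    wald_ratios,
    weighted_median,
)
from hcymr.summary_data import HarmonizedDataset, ValidationError
from hcymr.synthetic import SyntheticConfig, generate_dataset


def wls_through_origin(ds):
    """Independent oracle: weighted regression of bY on bX without intercept,
    weights 1/seY^2 (the IVW estimate's regression formulation)."""
    fit = sm.WLS(ds.beta_outcome, ds.beta_exposure, weights=1.0 / ds.se_outcome**2).fit()
    return float(fit.params[0])


class TestWaldRatios:
    def test_strongest_instrument_ratio_and_weight(self, nafld_ds):
        """rs1801133 (MTHFR): 0.063/0.1583 and weight (0.1583/0.042)^2."""
        wr = wald_ratios(nafld_ds)
        i = wr.snps.index("rs1801133")
        assert wr.ratio[i] == pytest.approx(0.063 / 0.1583, rel=1e-12)
        assert wr.ratio[i] == pytest.approx(0.3980, abs=5e-4)
        assert wr.weight[i] == pytest.approx((0.1583 / 0.042) ** 2, rel=1e-12)
        assert wr.weight[i] == pytest.approx(14.21, abs=0.01)

    def test_zero_outcome_beta_gives_zero_ratio_finite_weight(self, nafld_ds):
        wr = wald_ratios(nafld_ds)
        i = wr.snps.index("rs4660306")
        assert wr.ratio[i] == 0.0
        assert np.isfinite(wr.weight[i]) and wr.weight[i] > 0

    def test_zero_exposure_beta_rejected_by_name(self, toy_ds):
        toy_ds.beta_exposure[1] = 0.0
        with pytest.raises(ZeroDivisionError, match="rs2"):
            wald_ratios(toy_ds)

    def test_weights_are_inverse_squared_ratio_se(self, nafld_ds):
        wr = wald_ratios(nafld_ds)
        np.testing.assert_allclose(wr.weight, 1.0 / wr.se_ratio**2, rtol=1e-12)


class TestIVW:
    @pytest.mark.parametrize(
        "fixture, or_pub, lo_pub, hi_pub",
        [
            ("nafld_ds", 1.264, 0.924, 1.728),
            ("nash_ds", 1.891, 0.509, 7.022),
            ("cirrhosis_ds", 0.811, 0.498, 1.322),
        ],
    )
    def test_reproduces_published_liver_estimates(self, request, fixture, or_pub, lo_pub, hi_pub):
        """Multiplicative random-effects IVW on the homocysteine instruments
        reproduces the published odds ratios and CIs for all three outcomes."""
        ds = request.getfixturevalue(fixture)
        eff = ivw(ds, model="multiplicative_random")
        assert eff.or_scale == pytest.approx(or_pub, abs=0.005)
        assert eff.ci_low == pytest.approx(lo_pub, abs=0.005)
        assert eff.ci_high == pytest.approx(hi_pub, abs=0.02)

    def test_fixed_and_random_share_point_estimate(self, cirrhosis_ds):
        f = ivw(cirrhosis_ds, model="fixed")
        r = ivw(cirrhosis_ds, model="multiplicative_random")
        assert f.estimate_log == r.estimate_log
        assert r.se_log >= f.se_log  # dispersion never shrinks the SE

    def test_underdispersed_data_fall_back_to_fixed_se(self, nafld_ds):
        # NAFLD heterogeneity is below expectation (Q < J-1), so the
        # multiplicative factor floors at 1 and both models coincide
        q, _ = cochran_q(nafld_ds)
        assert q < nafld_ds.n_snps - 1
        assert ivw(nafld_ds, "fixed").se_log == ivw(nafld_ds, "multiplicative_random").se_log

    def test_single_snp_equals_wald_ratio(self, nafld_ds):
        one = nafld_ds.subset(["rs1801133"])
        eff = ivw(one, model="fixed")
        assert eff.estimate_log == pytest.approx(0.063 / 0.1583, rel=1e-12)
        assert eff.se_log == pytest.approx(0.042 / 0.1583, rel=1e-12)

    def test_agrees_with_wls_through_origin_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            cfg = SyntheticConfig(
                n_snps=int(rng.integers(3, 20)),
                theta=float(rng.normal(0, 0.5)),
                seed=int(rng.integers(2**31)),
            )
            ds = generate_dataset(cfg)
            assert ivw(ds, "fixed").estimate_log == pytest.approx(
                wls_through_origin(ds), abs=1e-12
            )

    def test_unknown_model_rejected(self, nafld_ds):
        with pytest.raises(ValidationError):
            ivw(nafld_ds, model="additive_random")


class TestWeightedMedian:
    def test_midpoint_interpolation_matches_hand_oracle(self):
        """theta (0.1, 0.2, 0.6), weights (0.2, 0.3, 0.5): midpoint cumulative
        weights are (0.1, 0.35, 0.75), so the 50% point interpolates between
        0.2 and 0.6 at (0.5-0.35)/0.4 of the way: 0.35."""
        est = _weighted_median_point(np.array([0.1, 0.2, 0.6]), np.array([0.2, 0.3, 0.5]))
        assert est == pytest.approx(0.35, rel=1e-12)

    def test_constant_ratios_return_constant(self):
        ds = HarmonizedDataset(
            snps=["rs1", "rs2", "rs3"],
            beta_exposure=np.array([0.1, 0.2, 0.4]),
            se_exposure=np.array([0.01, 0.01, 0.01]),
            beta_outcome=np.array([0.05, 0.10, 0.20]),  # all ratios 0.5
            se_outcome=np.array([0.03, 0.04, 0.05]),
        )
        assert weighted_median(ds, n_boot=50, seed=0).estimate_log == pytest.approx(0.5, rel=1e-12)

    def test_bootstrap_is_seeded_and_stable(self, nafld_ds):
        a = weighted_median(nafld_ds, n_boot=1000, seed=1)
        b = weighted_median(nafld_ds, n_boot=1000, seed=1)
        c = weighted_median(nafld_ds, n_boot=1000, seed=2)
        assert a.se_log == b.se_log  # identical seed, identical bootstrap
        assert a.estimate_log == c.estimate_log  # point estimate seed-free
        assert c.se_log == pytest.approx(a.se_log, rel=0.10)

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            ds = generate_dataset(SyntheticConfig(n_snps=8, theta=0.2, seed=int(rng.integers(2**31))))
            wr = wald_ratios(ds)
            est = weighted_median(ds, n_boot=10, seed=0).estimate_log
            assert wr.ratio.min() <= est <= wr.ratio.max()

    def test_requires_three_instruments(self, nafld_ds):
        with pytest.raises(ValidationError):
            weighted_median(nafld_ds.subset(["rs1801133", "rs2275565"]), n_boot=10, seed=0)
        with pytest.raises(ValidationError):
            weighted_median(nafld_ds, n_boot=1, seed=0)


class TestMREgger:
    def test_matches_statsmodels_wls_oracle(self, toy_ds):
        """Slope/intercept equal the normal-equation WLS fit; SEs equal the
        WLS SEs times the dispersion floor."""
        res = mr_egger(toy_ds)
        sign = np.where(toy_ds.beta_exposure < 0, -1.0, 1.0)
        x = toy_ds.beta_exposure * sign
        y = toy_ds.beta_outcome * sign
        fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / toy_ds.se_outcome**2).fit()
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.slope == pytest.approx(fit.params[1], abs=1e-10)
        # statsmodels scales the covariance by RSS/(J-2) without the floor;
        # undo both dispersions to compare the unscaled covariance
        unscaled = np.sqrt(np.diag(fit.cov_params()) / fit.scale)
        assert res.se_intercept / res.dispersion == pytest.approx(unscaled[0], rel=1e-10)
        assert res.se_slope / res.dispersion == pytest.approx(unscaled[1], rel=1e-10)

    def test_intercept_constrained_to_zero_reproduces_ivw(self):
        """Dropping the intercept column from the Egger design gives exactly
        the IVW estimate (regression-through-origin equivalence)."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            ds = generate_dataset(SyntheticConfig(n_snps=10, theta=0.3, seed=int(rng.integers(2**31))))
            constrained = sm.WLS(
                ds.beta_outcome, ds.beta_exposure, weights=1.0 / ds.se_outcome**2
            ).fit()
            assert constrained.params[0] == pytest.approx(ivw(ds, "fixed").estimate_log, abs=1e-12)

    def test_liver_outcome_intercepts_consistent_with_no_pleiotropy(
        self, nafld_ds, nash_ds, cirrhosis_ds
    ):
        """The pleiotropy intercept does not significantly differ from zero
        for any of the three liver outcomes."""
        for ds in (nafld_ds, nash_ds, cirrhosis_ds):
            assert mr_egger(ds).intercept_pvalue > 0.05

    def test_null_generator_gives_near_zero_intercepts(self):
        pvals, ints = [], []
        for s in range(40):
            ds = generate_dataset(SyntheticConfig(n_snps=50, theta=0.2, sign_random=False, seed=s))
            r = mr_egger(ds)
            pvals.append(r.intercept_pvalue)
            ints.append(r.intercept)
        assert abs(np.mean(ints)) < 0.005  # unbiased near zero
        assert np.mean(np.array(pvals) < 0.05) < 0.2  # not systematically small

    def test_no_leverage_rejected(self):
        ds = HarmonizedDataset(
            snps=["rs1", "rs2", "rs3"],
            beta_exposure=np.array([0.1, 0.1, -0.1]),
            se_exposure=np.array([0.01] * 3),
            beta_outcome=np.array([0.02, 0.03, 0.04]),
            se_outcome=np.array([0.05] * 3),
        )
        with pytest.raises(ValidationError, match="leverage"):
            mr_egger(ds)


class TestSharedProperties:
    @given(flip_idx=st.sets(st.integers(0, 11), max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_sign_symmetry(self, nafld_ds, flip_idx):
        """Negating (bX, bY) jointly for any SNP subset leaves IVW,
        weighted-median and Egger-slope point estimates unchanged."""
        flipped = HarmonizedDataset(
            snps=list(nafld_ds.snps),
            beta_exposure=nafld_ds.beta_exposure.copy(),
            se_exposure=nafld_ds.se_exposure,
            beta_outcome=nafld_ds.beta_outcome.copy(),
            se_outcome=nafld_ds.se_outcome,
        )
        idx = list(flip_idx)
        flipped.beta_exposure[idx] *= -1
        flipped.beta_outcome[idx] *= -1
        assert ivw(flipped, "fixed").estimate_log == pytest.approx(
            ivw(nafld_ds, "fixed").estimate_log, rel=1e-12
        )
        assert weighted_median(flipped, n_boot=2, seed=0).estimate_log == pytest.approx(
            weighted_median(nafld_ds, n_boot=2, seed=0).estimate_log, rel=1e-12
        )
        assert mr_egger(flipped).slope == pytest.approx(mr_egger(nafld_ds).slope, rel=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, -1.5])
    def test_scale_equivariance(self, c, nafld_ds):
        scaled = HarmonizedDataset(
            snps=list(nafld_ds.snps),
            beta_exposure=nafld_ds.beta_exposure,
            se_exposure=nafld_ds.se_exposure,
            beta_outcome=c * nafld_ds.beta_outcome,
            se_outcome=nafld_ds.se_outcome,
        )
        assert ivw(scaled, "fixed").estimate_log == pytest.approx(
            c * ivw(nafld_ds, "fixed").estimate_log, rel=1e-12
        )
        assert mr_egger(scaled).slope == pytest.approx(c * mr_egger(nafld_ds).slope, rel=1e-12)
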