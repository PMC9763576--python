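# Methods

## Setting and model

The package estimates the causal effect of a quantitative exposure
(plasma homocysteine) on binary outcomes (NAFLD, NASH, Cirrhosis) from
two-sample GWAS summary statistics.  The structural model behind every
estimator is linear on the log-odds scale:

    beta_Y_j = theta * beta_X_j + alpha_j,        j = 1..J instruments

where theta is the causal log odds ratio per unit exposure and alpha_j is
SNP j's direct (horizontal-pleiotropy) effect on the outcome.  A valid
instrument has alpha_j = 0 (exclusion restriction), is associated with the
exposure (relevance; enforced by the p < 5e-8 filter) and is independent
of confounders.  Because the exposure and outcome GWAS share no samples,
estimation errors in beta_X and beta_Y are independent — the two-sample
design the generator and the bootstrap both honour.

The exposure's unit is treated as opaque ("per unit homocysteine"): the
source tables do not state whether effects are per µmol/L or per SD, and
nothing downstream depends on it.

## Estimators and conventions

**Wald ratios.**  theta_j = beta_Y_j / beta_X_j with first-order
delta-method SE s_Yj / |beta_X_j|, giving IVW weight
w_j = beta_X_j^2 / s_Yj^2.  Exposure-side uncertainty is ignored in the
weights (the standard first-order convention, and the one consistent with
the reproduced results); the calibration experiments below quantify the
residual effect at realistic instrument strength.

**IVW.**  Weighted mean of the ratios; algebraically identical to WLS of
beta_Y on beta_X through the origin with weights 1/s_Y^2 (asserted to
1e-12 in the tests).  Two dispersion models are provided:

* `fixed`: se = 1/sqrt(sum w_j);
* `multiplicative_random` (default): that SE times max(1, sqrt(Q/(J-1))),
  Q = Cochran's heterogeneity statistic.

The default follows the convention of the standard R implementation for
J >= 4, and it is the model that reproduces the published CI bounds for
all three liver outcomes: for NAFLD Q/(J-1) < 1 and the two models
coincide (OR 1.263, CI 0.923–1.728), while the NASH and Cirrhosis CIs
(0.509–7.007 and 0.498–1.319) require the dispersion factors 1.051 and
1.132.  A fixed-effect-only reading would reproduce the NAFLD row but not
the other two.

**Weighted median.**  The ordered ratios' 50%-cumulative-weight point
with the midpoint convention s_j = cumsum(w)_j − w_j/2 and linear
interpolation — the dominant convention in the MR literature; the
trailing-sum alternative differs only at small J.  The SE is the SD of
the estimate over a parametric bootstrap (default 1000 draws)
resampling beta_X* ~ N(beta_X, s_X) and beta_Y* ~ N(beta_Y, s_Y); a seed
is required in pipeline configs so reports are byte-reproducible.

**MR-Egger.**  Instruments are first oriented so beta_X_j > 0 (negating
both betas leaves every ratio unchanged but makes the intercept
identifiable).  The fit is 2-parameter WLS with weights 1/s_Y^2, solved by
the normal equations so the SE convention is explicit: covariance scaled
by max(1, sqrt(RSS/(J-2))), the same multiplicative floor as IVW.  The
intercept estimates mean directional pleiotropy per SNP and is tested
two-sided against the standard normal.  The slope is a consistent causal
estimate only under InSIDE (pleiotropy independent of instrument
strength).

**MR-PRESSO.**  Residuals are taken about leave-one-out IVW predictions
(theta_hat_{-j} * beta_X_j) so an outlier cannot mask itself; the weighted
convention is r_j^2 / s_Yj^2.  The global test compares observed total
RSS with RSS from datasets simulated as beta_Y*_j ~ N(theta_hat_{-j} *
beta_X_j, s_Yj), each simulated dataset re-analysed with its own
leave-one-out estimates.  Outcome-side noise only is simulated by
default (exposure-side simulation available via flag; at these SE scales
the difference is negligible).  The per-SNP outlier test compares each
observed weighted squared residual with that SNP's simulated
distribution, Bonferroni-corrected across J at level 0.05; the corrected
estimate is fixed-effect IVW on the non-flagged SNPs when >= 3 remain,
otherwise an explicit too-few-SNPs flag is set.  The distortion statistic
is the relative shift of the IVW estimate after outlier removal, with an
empirical p from random same-size removals.  All empirical p-values use
(count+1)/(n_sim+1), so they live in [1/(n_sim+1), 1] and are never 0.

**P-values and CIs** throughout use the standard normal (z), not t:
that is the convention the reproduced results imply (NAFLD p = 0.144).

## Instrument selection

Selection is three composable steps: p < 5e-8 thresholding; greedy LD
pruning against a user-supplied local r-squared matrix (visit candidates
by ascending p, rsid tie-break; accept iff r² with every accepted SNP is
below threshold, default 0.05); and an explicit rsid exclusion list
(covering both "no outcome information" and confounder-screen removals).
No web services are queried.  The packaged candidate walk-through
(18 → 15 → 12) uses synthetic stand-ins — labelled `_synthetic` — for the
six removed candidates and for the LD matrix, because the source reports
which rsids were removed but not their statistics; the analysis fixture
itself is the published 12-row table verbatim.  That table carries a
known bookkeeping oddity inherited from the source: rs12780845 appears
both among the information-lacking exclusions and in the final
12-instrument table; the fixture follows the table, under which all
published estimates reproduce.

## Allele harmonization

Outcome records are aligned to the exposure's effect allele: identical
alleles pass through; swapped effect/other alleles negate the outcome
beta (flip logged); any other pair is dropped with a warning.
Palindromic (A/T, C/G) SNPs cannot be strand-checked without frequencies,
so the default policy keeps and flags them (the packaged table was
analysed in full); `drop` is available for general inputs.
Harmonization is idempotent, and a double allele flip is an identity —
both are property-tested.

## Synthetic generator

`SyntheticConfig` draws |beta_X| ~ U(0.04, 0.16), s_X ~ U(0.007, 0.013)
and s_Y ~ U(0.037, 0.063) — the magnitude ranges of the packaged
homocysteine/liver tables (a 44k-sample quantitative exposure GWAS
against rare binary outcomes in a ~300k biobank) — with J = 12 and
theta defaulting per experiment (0 for null calibration, 0.234, the
NAFLD-scale log estimate, for coverage).  Pleiotropy regimes: `none`;
`balanced` alpha ~ N(0, tau); `directional` alpha ~ N(mu, tau); an
`inside_violation` parameter correlates alpha with instrument strength to
break InSIDE.  Exposure-effect signs are random by default; directional-
pleiotropy experiments set `sign_random=False`, since with randomly
signed instruments a constant alpha cancels under Egger orientation
rather than appearing as an intercept.  A planted outlier shifts one
observed outcome beta by a stated multiple of its SE.

The generator emulates summary statistics only.  It does not model
case/control sampling (rare-outcome realism enters solely through large
outcome SEs), LD between instruments, winner's-curse selection of
instruments, or non-Gaussian estimation error — so passing calibration
here shows the estimators are correct under the stated model, not that
real-data violations of that model are harmless.

## Numerical and design choices

* Empirical-p floor (count+1)/(n_sim+1); Bonferroni outlier threshold
  0.05/J; PRESSO requires J >= 4, median and Egger J >= 3.
* Exact-zero exposure betas raise by rsid (Wald ratio undefined);
  exact-zero *resampled* betas in bootstrap/simulation are nudged to the
  smallest positive float rather than discarded, preserving draw counts.
* Greedy pruning keeps the smaller exposure p of a correlated pair —
  the standard clumping convention, deterministic via the rsid tie-break.
* LD threshold default 0.05 (the stricter of the two thresholds the
  source states); any value in [0, 1] is accepted.
* Multiple-testing correction across outcomes is deliberately not
  applied, matching per-outcome reporting conventions.
* Report TSVs are written with a fixed float format; identical config and
  seed give byte-identical files (tested).
* Problem sizes for the simulation experiments (500 replicates for
  calibration/coverage, 100 planted-outlier and 200 null PRESSO
  replicates at 500 simulations each) give binomial Monte-Carlo error
  well inside the asserted bands while keeping the whole suite around
  twenty seconds on one core.

## Limitations

Beyond the generator's simplifications above: the weighted-median SE is
bootstrap-based and therefore seed-dependent (at 1000 draws the SE of the
SE is ~2%); MR-PRESSO's simulated null does not replicate any particular
published implementation's RNG stream (results agree in distribution,
not bitwise); and the pipeline estimates a single exposure→outcome
direction — multivariable, bidirectional and mode-based estimators are
out of scope.
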