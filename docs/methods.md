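# Methods

## Response model

Background Cd concentrations in mosses live in a bounded interval
(0, Cd_max) with Cd_max = 1.5 µg/g, the maximal value expected for
background forest samples. The complementary log–log transform

    z = ln(ln(Cd_max / Y)),        Y = Cd_max · exp(−exp(z))

is the inverse Gumbel CDF applied to Y/Cd_max; it maps the interval onto
the whole real line, is strictly decreasing in Y (a covariate that raises
the concentration carries a **negative** coefficient on the z scale), and
guarantees that any back-transformed linear predictor is a valid
concentration. A Gaussian linear model is fitted to z by ordinary least
squares. Because the transform is nonlinear, `Cd_max·exp(−exp(η̂))` is the
conditional **median** of Y, not its mean; maps are therefore
median-scale, and no smearing/bias correction is applied. In floating
point, extreme linear predictors can under/overflow `exp`; the inverse
transform clips to the nearest representable value strictly inside the
open interval so the bound invariant survives numerically.

Assumptions: homoscedastic Gaussian noise on the transformed scale,
effects linear in the native covariate units (no standardisation —
coefficients are reported per percent, per metre, etc.), independent
errors (spatial dependence is diagnosed, not modelled).

## Covariate screening

1. **Zero filter.** A quantitative covariate is removed when its
   proportion of exact zeros on the rows in scope is *strictly greater*
   than 0.95 ("more than 95 %" read literally). Per-zone models evaluate
   the proportion on their own rows; the national model pools all rows by
   default (an `any_zone` mode that removes variables sparse in any
   single zone is also exposed, since either reading is defensible).
2. **Spearman filter** at |ρ| > 0.75, average ranks for ties.
   *Within a buffer family* (`Forest_1/5/10/15`, …): connected components
   of over-threshold pairs collapse onto the smallest-buffer member — the
   smallest buffer is the most local, least smoothed measurement.
   *Across families*: while any retained pair exceeds the threshold
   (worst pair first), the member with the larger mean absolute
   correlation to all other retained variables is removed; this
   operationalises "keep the less redundant variable" deterministically.
   Constant columns have no defined rank correlation and are removed up
   front with an explicit "undefined correlation" annotation.

## Model selection

Backward–forward stepwise minimisation of

    AIC = −2·loglik + 2·(k + 1),   loglik = −M/2·(ln 2πσ̂²_ML + 1)

where k counts mean parameters and the +1 the variance parameter (the
additive constant does not affect rankings; a test asserts ranking
equivalence with the RSS-based criterion). Each iteration scores every
single-variable drop and add and applies the single best move; iteration
stops when no move lowers the AIC, which guarantees termination because
accepted moves strictly decrease a bounded-below criterion. Categorical
variables move as whole dummy blocks (selection operates on *variables*,
not columns). Rank-deficient candidate fits are skipped and logged, not
fatal. When the full screened model itself is not estimable — typical for
a small zone with nearly as many covariates as observations — selection
starts from the intercept-only model with the same move rules instead of
failing. Reference levels are fixed (Hc moss, deciduous cover, Alpine
zone) so coefficient tables read as contrasts against the mapped
reference profile. Non-significant variables that lower the AIC are kept;
no significance pruning is layered on top.

Selection is performed **once** on the full data; LOOCV refits only the
coefficients. Re-running selection inside each fold would make the single
reported variable list meaningless, at the cost of a mild optimism in the
regression LOOCV score — a documented caveat, not a hidden one.

## Moran diagnostics

Global Moran's I with binary, symmetrised k-nearest-neighbour weights
(k = 8) — robust to the irregular density of survey sites; inverse-distance
and row-standardised variants are options. Significance uses a
permutation test (999 permutations, add-one estimator) rather than the
normal approximation, which keeps the test valid at the smallest zone
sizes (~29 sites). The default alternative is one-sided "greater" —
does clustering persist? — with p = (1 + #{perm I ≥ obs})/(n_perm + 1),
which is uniform under the null; "less" and a doubled "two-sided" are
options. (A tail chosen from the observed sign would double the type-I
error to ~0.10 and is deliberately not offered as a default.)
A `halve` flag reproduces, on request only, the non-standard
convention of reporting I/2 seen in some published tables; the package
neither interprets nor defaults to it. OLS residuals carry a small
hat-matrix-induced negative bias of order k/M; the calibration test
(rejection rate within [0.02, 0.09] at nominal 0.05 over 200 replicates)
shows this is negligible at the sizes used.

## Prediction maps

For each grid cell, η̂(s) = x(s)'b with categoricals fixed at the
reference profile (species and cover from the profile, zone from the grid
where the model uses it), se_η from the coefficient covariance
(unbiased-σ² scaling), and

    ŷ(s) = Cd_max·exp(−exp(η̂)),   sd_ŷ = Cd_max·exp(η̂ − exp(η̂))·se_η

by the delta method. The default SD is that of the *fitted mean*,
matching the usual predict-then-delta behaviour of regression software; a
flag adds the residual variance for a prediction-scale SD. Cells whose
covariates fall outside the training min/max are flagged `extrapolated`
rather than masked — forest-calibrated models extrapolating into urban
cells is a real limitation the flag makes visible. Per-zone maps are
mosaicked by concatenation with a hard error if any cell is claimed by
zero or multiple zones.

## Ordinary-kriging baseline

Observations are log-transformed (they are positive and right-skewed),
the empirical semivariogram uses the classical Matheron estimator with
equal-width distance bins up to half the maximum distance (custom edges
accepted; the reported lag of a bin is its mean pair distance, which
keeps short-lag bins honest when close pairs exist), and a parametric
model — exponential by default, with the practical-range convention
γ(h) = c₀ + c·(1 − e^(−3h/a)) — is fitted by weighted least squares with
pair counts as weights. The OK system (zero diagonal, unit-sum constraint
via a Lagrange multiplier) is factorised once per site set and solved for
all cells; a singular system (duplicate sites with zero nugget) triggers
one jitter-and-retry before failing. Back-transform is simple
exponentiation — a median-type map consistent with the regression map's
semantics; the known lognormal bias of this choice is accepted and
documented. Kriging SDs are delta-method propagated (ŷ·sd_log). All
sites enter every system up to 500 sites; beyond that the nearest 64.

A known limitation quantified during testing: with ~300 sites, the
sampling distribution of the *nugget* (and to a lesser degree the range)
of a fitted variogram is wide even for an exact maximum-likelihood
estimator; only the sill is reliably recovered to tight tolerances. The
recovery simulation therefore uses a close-pair sampling design (each of
150 random sites twinned a few hundred metres away), the standard design
when nugget estimation matters, and the acceptance suite reports the
recovery rate it actually achieves.

## LOOCV

For each site, coefficients (or kriging weights) are recomputed from the
remaining M−1 sites — variable set and variogram held fixed — and the site
is predicted on the concentration scale; RMSE = √(Σ(y−ŷ)²/M) in µg/g. On
the transformed scale these refits coincide with the closed-form
leave-one-out identity for linear smoothers (asserted as an internal
oracle); on the concentration scale explicit refits are what the reported
score uses. A fold whose training set loses a categorical level present
only at the held-out site predicts that site from the reference profile
and is flagged and counted. Zone-wise scores of the national model come
from splitting its per-site held-out predictions by zone; pooled
national scores of the zone models use the exact identity
√(Σ M_z·rmse_z² / Σ M_z).

## Synthetic campaign generator

The generator emulates the design of a 445-site national survey: four
rectangular biogeographical zones (site shares 220/147/49/29) in an
abstract planar CRS (only distances matter to the analysis), five moss
species at frequencies 227/186/27/4/1 of 445, four tree-cover classes,
and ~52 quantitative covariates. Latent fields are Gaussian processes
approximated by 96 random Fourier features, making each field a
deterministic function of location — sites and grid cells evaluated at
the same coordinates agree exactly, which is what makes shared-field
prediction grids coherent. Buffer families mix a common base field with
member-specific jitter; the mixing weight is derived from the configured
Spearman target through the bivariate-normal relation ρ_S = (6/π)asin(ρ/2)
plus a safety margin, so monotone transforms keep the realised rank
correlation above target. Land-use percentages are probit-transformed to
[0, 100]; distances and concentration-like covariates are lognormal.
Zero inflation thresholds the latent field at the corresponding normal
quantile, producing spatially coherent zeros (sea shares are zero inland,
not speckled); consequently the realised zero proportion fluctuates
around the target between field realisations rather than being exact.
All randomness flows from one seed through named substreams
(fields/coordinates/species/tree/noise/grid), so each stage is
individually reproducible.

Default true effects are set on the transformed scale with signs matching
the survey literature (air concentration, soil Cd, urban share raising
Cd; sea share and agricultural share lowering it; species and cover
offsets against Hc/deciduous) and magnitudes chosen once so that the
linear predictor's spread is comparable to the noise SD σ = 0.3 — a
realistic signal-to-noise for a national survey. What the generator does
**not** emulate: real geometry, measurement error structure of ICP-MS,
non-Gaussian noise, covariate measurement artefacts, or spatially
correlated residuals beyond what the covariate fields induce. Passing
tests therefore establish the correctness and calibration of the
machinery under the stated model, not the field validity of any
particular covariate's effect.

## Numerical choices and problem sizes

- OLS via statsmodels on an explicitly built design matrix; rank is
  checked first and singular designs fail loudly listing aliased columns
  (SVD null space). Exact fits (σ̂² = 0) report p-values by the
  zero-coefficient convention instead of NaN.
- Strict-decrease tolerance for stepwise moves: 1e-10 on the AIC; ties
  between equal-AIC moves break by variable name.
- Variogram WLS runs bounded `least_squares` from moment-based starts;
  kriging variances are clipped at zero against −1e-12-scale round-off.
- Tests and the acceptance script size simulations at n = 100–445 with
  50–200 replicates, the full campaign at its native 445 sites, grids at
  20–60 km cells (the analysis is resolution-agnostic); the whole suite
  runs in well under a minute.
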