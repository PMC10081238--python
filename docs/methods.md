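# Methods

## Model and procedure

The unit operation is an ordinary-least-squares association test between
one biological marker and one phenotype. The default orientation is the
EWAS convention, marker ~ intercept + outcome + covariates, with the
reported coefficient, t statistic and two-sided p referring to the
outcome term; the reverse orientation (outcome as response) is exposed
and, without covariates, yields the identical t statistic — both equal
the Pearson-correlation t — so either is a valid basis for the fold
meta-analysis. Binary phenotypes are treated as 0/1 numeric regressors in
the linear model. The intercept is always included, and fits demand
complete cases: row-wise deletion is the reader's responsibility
(`robustewas.io`), never performed silently inside a fit.

The robust scan partitions the n samples into k equal, non-overlapping
folds (sizes differ by at most one; the first n mod k folds take the
extra sample), fits the full covariate-adjusted model separately within
each fold, maps each fold t to a signed Z through the exact t-tail, and
combines with equal-weight Stouffer:

    z_i    = sign(t_i) * Phi^-1(1 - P(T_df_i > |t_i|))
    z_meta = sum(z_i) / sqrt(k),   p_meta = 2 * Phi(-|z_meta|)

Two numerical choices matter here. First, the t->Z map uses the exact
tail, not the identity z ~= t: per-fold residual degrees of freedom are
small (fold size minus fitted coefficients) and the heavier t tails would
otherwise inflate the meta statistic. The tail is computed on the log
scale (`scipy.special.ndtri_exp` of the log survival function) so
statistics as extreme as |t| ~ 80 map without underflow. Second,
covariates are refit within every fold. The tempting shortcut —
residualize covariates once on the whole sample, then test per fold while
charging the lost degrees of freedom across folds — deflates p-values,
because whole-sample residualization leaks information between folds; it
is excluded by design, as is log-transforming the data (results for
transformed data need not transfer to the original scale).

Equal Stouffer weights are the default because folds are constructed
equal-sized, making sqrt(n_i) weighting equivalent up to the unavoidable
±1; a weights argument exists for deliberately uneven folds.

When the outcome is binary, fold assignment is stratified on it by
default (each class dealt round-robin into folds), since an all-control
fold makes the per-fold test undefined. A minimum-fold-size guard
(default: covariate count + 3) rejects k too large for valid fits.

## Comparators

*Full-sample analysis* is the k=1 semantics reported on the native t
scale; `robust_ewas(k=1)` matches it exactly on the Z scale (asserted to
1e-12 in tests).

*Split-half replication* randomly splits the sample 50/50 (stratified on
a binary outcome), tests two-sided in the discovery half at
alpha_discovery, and for markers passing discovery runs a one-sided test
in the replication half in the discovery direction at alpha_replication.
Two type-I metrics are emitted, because the headline rate of a two-stage
procedure is genuinely ambiguous: the **conditional** replication rate
among discoveries (nominal level alpha_replication) and the **joint**
declaration rate (nominal alpha_d * alpha_r). The conditional rate is
used as the compared metric in the acceptance checks and the joint rate
as the split-half power metric (a marker that never reaches replication
is undetected). Both are always in the output so users can choose.

## Diagnostics

Genomic inflation lambda is median(observed chi-square_1) / 0.4549364,
with p-values converted through the upper-tail chi-square_1 quantile;
exact zeros map to the largest finite quantile with a warning. MAD
outlier flags use the robust z-score |r - median(r)| / (1.4826 * MAD(r))
with threshold 3 by default; the 1.4826 normal-consistency constant makes
"MAD > 3" the conventional robust-3-sigma rule (the bare phrase is
ambiguous between raw and scaled MAD; the scaled reading is adopted and
documented). Zero MAD is a degenerate-spread condition: nothing is
flagged, a warning is emitted, and no division occurs.

The outlier-sensitivity refit audits a significant marker by flagging
MAD outliers on the residuals of the very model whose p-value is in
question, refitting without them, and reporting p_trimmed / p_full. A
finding is labelled outlier-driven when that ratio exceeds 100 — i.e. the
evidence *weakens* at least 100-fold on removal. The direction of the
rule is part of the output (`outlier_driven` plus both p-values) so it
can be audited; the package deliberately does not auto-remove flagged
samples from primary analyses — per-site post-hoc removal is exactly the
unsystematic practice the fold meta-analysis replaces.

## Simulation design

The Monte-Carlo study draws replicate (outcome, marker) pairs as standard
bivariate normals via x = rho*y + sqrt(1-rho^2)*eps. Defaults are the
study conditions: n = 250 individuals, 10,000 replicates, alpha = 0.05
with rho = 0 for type-I error, alpha = 0.001 with rho = 0.3 for power,
five univariate or one bivariate outlier, and a fold grid
{2, 5, 10, 20, 25} bracketing k=10 (fold size 25 at n=250).

Outliers **replace** values (nominal n stays fixed) with ±magnitude, the
population being standard normal. Three quantities the design leaves
open are parameterized with documented defaults:

* **magnitude** — default 6 SD, large enough to dominate a fold-level fit
  at fold size ~25 yet plausible for an array artefact; magnitude-
  dependent checks are run across {4, 6, 8} SD;
* **univariate variable assignment** — the five affected individuals
  alternate between marker and outcome (a 3/2 split), the starting
  variable random by default and configurable; an individual never has
  both variables altered;
* **bivariate sign scheme** — concordant (same sign on both variables) by
  default, since only concordant extremes manufacture spurious
  association; discordant is available.

The engine is vectorized across replicates: with one marker and no
covariates every analysis reduces to Pearson-correlation t statistics on
(sub)samples, and the suite asserts exact replicate-level agreement
between this path and the statsmodels OLS path (including a whitebox
replay of the fold permutation against `meta_analyze_marker`). All
randomness derives from a single integer seed through named substreams
(data, outliers, fold assignment keyed additionally by k, split-half), so
enlarging the method grid never perturbs the data or another method's
assignment, and a full `SimResult` is bit-reproducible from (config,
seed). Reported rates are exact counts over trials; the Monte-Carlo
standard error sqrt(r(1-r)/n_trials) uses the trials the metric actually
consumed — 10,000 for full/robust/joint rates, the number of discoveries
(about alpha * 10,000) for the split-half conditional rate, whose
sampling band is therefore about 4.5 times wider.

`generate_fixture_ewas` builds m-feature integration fixtures with known
truths. One deliberate deviation from the single-marker design: the
outcome vector is shared across features, so per-feature "bivariate"
fixture outliers do not mutate the outcome; instead the extreme marker
value is placed on the individuals whose outcomes are already most
extreme, reproducing the hazardous same-individual double-extreme
pattern. The generator emulates independent Gaussian markers with
optional shared covariate loadings; it does not emulate beta-value
heteroscedasticity, probe-level batch effects, or correlated nulls, so
calibration results on it speak to the statistics, not to array
preprocessing.

## What the simulations show

With no outliers all methods hold the 5% level, and the robust scan at
k=5 loses only ~0.01 absolute power at rho=0.3. Five univariate outliers
pull full-sample type-I error *below* nominal (they inflate the marker
variance, attenuating t) while robust k=10 stays at 5%; in the power
setting the same attenuation costs the full-sample test far more than the
fold meta-analysis (at 8 SD: 0.32 vs 0.63 measured), because attenuation
is confined to the affected folds. One concordant 6-SD bivariate outlier
inflates the full-sample rate to ~0.52 while robust inflation falls
monotonically in k (0.43, 0.28, 0.17, 0.10 at k = 2, 5, 10, 20).

For split-half under a bivariate outlier the two emitted metrics
disagree about severity: the *conditional* replication rate saturates
near 0.07 regardless of magnitude — discoveries are dominated by
outlier-in-discovery replicates whose replication half is clean, so the
conditional rate tends to (P_disc*alpha + alpha*P_rep)/(P_disc + alpha) —
while the *joint* rate, set against its nominal 0.0025, is inflated
roughly twelvefold, worse than the full-sample inflation at the default
magnitude. The acceptance test compares the conditional metric and is
accordingly expected to fail its split-half-versus-full leg; the tests
measuring both metrics and the fold monotonicity pass. Split-half joint
power is the lowest of all methods in every scenario measured, driven by
discovery-stage power at half the sample size.

## Problem sizes and tolerances

The acceptance tests run the full design (10,000 replicates, n=250);
unit-level Monte-Carlo oracles use 400–20,000 trials as noted per test.
Stochastic assertions use five binomial standard errors at the metric's
trial count (±0.011 for a 5% rate over 10,000 trials). Exact identities
(k=1 reduction, t->Z p preservation, Stouffer closed forms) are asserted
at 1e-12; lambda grid identities at 1e-3. Degenerate inputs — constant
tested variable, rank-deficient covariates, folds below the minimum size,
empty meta input, zero MAD, p=0 — raise typed errors or warn, as
documented on each function.

## Known limitations

Linear association only (no GLM/mixed models, no surrogate-variable or
cell-composition adjustment); single-marker tests with independent nulls
in simulation; no weighted or random-effects meta-analysis across
heterogeneous studies (folds are exchangeable subsamples, not studies);
no array preprocessing (IDAT/normalization/QC are upstream). The fold
meta-analysis is not cross-validation: no prediction crosses folds.
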