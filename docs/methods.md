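# Methods

This note documents the models the package fits, the numerical choices
behind them, and what the synthetic cohorts do and do not emulate. It
is the design record for maintainers; empirical statements below are
limited to what the test suite and `scripts/acceptance.py` themselves
compute.

## Scientific setting

The package targets a recurring design in cerebrovascular ageing
research: a cross-sectional cohort of healthy older (HO) and mild
cognitive impairment (MCI) participants carrying (i) a neuropsychological
battery, (ii) white-matter-lesion (WML) volumes from FLAIR segmentation,
normalized by total intracranial volume (TIV) and expressed in percent
(`wml_ratio = 100 * WML / TIV`), and (iii) resting-state functional
connectivity summarized as Fisher-z ROI-to-ROI correlations within
canonical networks (fronto-parietal, salience, default mode). The
scientific question is whether connectivity in cognitive control
networks buffers (moderates) the detrimental association of lesion load
with cognition — a neural implementation of cognitive reserve — and
whether vascular risk acts on cognition through lesion load
(mediation).

## Measurement models

Cognition is modeled as a general factor `g` measured by all ten test
scores, with *nested* executive (`ef`: trail making A/B, Stroop
interference) and memory (`memory`: verbal learning immediate/delayed/
recognition) factors explaining residual shared variance of their
subsets over and above `g`. Nested factors are orthogonal to `g` and to
each other — the standard identification for nested/bifactor
structures; the alternative (correlated specific factors) is not
identified with this indicator allocation. Timed executive scores are
negated first (`invert_speed_scores`) so that higher always means
better; negation rather than a reciprocal preserves the linearity of
the factor model.

Each network's global connectivity is a single factor measured by the
network's ROI-pair Fisher-z values; pairs sharing a seed region may
carry residual covariances (the default study specification includes
the two default-mode pairs sharing the MPFC and PCC seeds).
Behavioral cognitive reserve is a three-indicator factor (education
years, premorbid IQ, lifestyle index) and is just identified.

Identification is per latent: `standardize_latent` (default) fixes the
latent variance — the *residual* variance for endogenous latents — to
1 with all loadings free; `fix_first_loading` fixes the first loading
to 1 instead. The default mirrors scaling latents by standardization;
for endogenous latents the unit-disturbance convention is what makes
generating and estimated structural coefficients directly comparable.

## Estimation: FIML linear SEM

The linear engine holds the model in reticular-action (RAM) form
`v = a + A v + u`, `u ~ N(0, S)`, giving implied moments
`mu = F(I-A)^{-1}a`, `Sigma = F(I-A)^{-1}S(I-A)^{-T}F'`. Missing data
are handled by the casewise (full-information) likelihood: subjects are
grouped by missingness pattern and contribute the Gaussian log-density
of their observed subvector. Exogenous observed predictors are brought
into the model with free means, variances, and covariances (saturated
within the exogenous block and against exogenous latents), so subjects
missing a predictor still contribute.

The log-likelihood gradient is analytic (matrix chain rule through the
RAM structure, per missingness pattern); optimization is L-BFGS on a
log-transformed parameterization keeping variances positive, with a
polish pass and up to five restarts (jittered starts) when the
gradient norm of the mean log-likelihood has not reached 1e-5. A
non-positive-definite implied covariance is rejected with a large
penalty during line search. Non-convergence is flagged on the result,
never silent. Standard errors come from the observed information
matrix (central differences of the analytic gradient).

The chi-square statistic is twice the gap to the saturated model,
which is itself estimated under the same missingness handling (closed
form for complete data, EM over patterns otherwise). The baseline for
CFI is the independence model, whose FIML solution factorizes per
variable and is closed form. Fit-index conventions (fixed here, one of
several in circulation): `chi2/df`; `rmsea = sqrt(max(chi2-df,0)/(df*n))`
with the analysis n; `cfi = 1 - max(chi2-df,0)/max(chi2_b-df_b,
chi2-df, 0)`; SRMR as the root mean square of residuals between the
model-implied moments and pairwise-complete sample moments,
standardized by observed variances (mean residuals included). With
df = 0 the ratio and RMSEA are reported as not applicable. Degrees of
freedom count means and covariances on both sides:
`df = p(p+1)/2 + p - free parameters`; negative df is rejected before
optimization.

Factor scores are regression-method (conditional expectation) scores
from the implied joint distribution of latents and observed variables;
partially observed subjects are scored from their observed subset.

## Latent moderated structural equations

The moderation model regresses latent outcomes on the observed lesion
load `w` (mean-centred), the moderator, and their product. With an
observed moderator both are centred, the product is a computed
regressor, and the model reduces exactly to linear SEM. With a latent
moderator `xi` the product `w * xi` makes the joint distribution
non-Gaussian; conditional on `xi` (and on the observed exogenous
variables) the system is linear-Gaussian, so the marginal likelihood
is a one-dimensional integral evaluated by fixed-node Gauss-Hermite
quadrature (default 16 nodes).

Node placement: plain prior-placed Gauss-Hermite nodes converge slowly
here, because with three well-measured indicators the moderator's
posterior is much narrower than its prior and subject-specific. The
default grid therefore places the nodes at each subject's posterior
location and scale, computed once at the starting values and then held
fixed (scale inflated 1.2x); the moderator's prior density enters the
integrand explicitly with the change-of-variables weights. Freezing
the grid keeps the objective smooth and the analytic gradient exact,
while 8 nodes are already accurate to ~1e-4 on the interaction
coefficient; the node-doubling diagnostic (`quadrature_shift`) is the
check that the count suffices. A plain prior-placed grid remains
available (`grid="prior"`).

Further conventions of the latent-moderator fit:

* the moderator is scaled by a unit *conditional* variance and by
  default regresses freely on the predictor; this reproduces the
  joint-Gaussian linear model exactly when the interaction is absent
  (the "reduction to linear SEM" oracle);
* exogenous observed variables (predictor, covariates) are conditioned
  on; rows missing them are dropped (matching common SEM-software
  handling of missing x variables), and their saturated Gaussian
  marginal is added to the reported log-likelihood so that LMS and
  joint-model linear likelihoods are directly comparable, including in
  likelihood-ratio tests;
* starting values come from the no-interaction linear solution, which
  also guarantees the nesting property (the interaction model's
  likelihood never falls below the constrained one);
* interaction p-values are Wald; likelihood-ratio tests are available
  through `chi2_difference` with the interaction fixed to zero.

Standard errors default to the observed information (negative Hessian
of the marginal log-likelihood, by central differences of the analytic
gradient). Conditional on `w` the marginal of each subject's observed
vector is exactly Gaussian with a rank-one covariance update
`Sigma + dir_i dir_i'`, so the expected (Fisher) information also has
a closed form and is available as `se_method="expected"`. Calibration
of the Wald interaction test at the study size is sensitive to full
optimizer convergence — the information about the product term is
concentrated in few high-leverage (high lesion load) subjects — which
is why the optimizer includes a polish restart and the suite measures
the type-I error of the test directly.

Simple slopes: the conditional slope of an outcome on the predictor at
moderator level ±1 SD is `b_predictor + b_interaction * level * SD`,
with the model-implied moderator SD (for a latent moderator,
`sqrt(1 + gamma^2 var(w))`); slope standard errors use the delta
method on the joint parameter covariance. `prediction_table` exports
centred predicted-score lines with confidence bands for plotting.

## Mediation

Vascular risk -> lesion load -> latent cognition is fitted as one
simultaneous SEM (paths a, b and the direct path c'); the indirect
effect is a*b by construction. The confidence interval is a seeded
nonparametric percentile bootstrap over subjects (default 2000 draws),
with the standardized indirect effect computed per draw from the
standardized paths; a delta-method (Sobel) interval is computed for
comparison. The percentile default reflects that resampling intervals
are asymmetric, as indirect-effect intervals typically are; refits
start at the full-sample solution and a result is flagged when more
than 5% of draws fail to converge.

## Multigroup latent interactions

Groups are known classes: one optimization maximizes the sum of the
per-group casewise likelihoods. By default measurement parameters
(loadings, indicator intercepts, indicator residual variances and
covariances) are constrained equal across groups while all structural
parameters — main effects, interactions, disturbances, the moderator's
regression on the predictor — are free per group; per-group Wald tests
use the joint information (block-additive across groups, expected
information for latent-moderator groups). Latent means are fixed at
zero in every group: this keeps the parameterization symmetric under
relabeling of groups (an invariant the suite checks) at the cost of
forcing equal latent means; `equal_measurement=False` releases all
equality constraints as the sensitivity analysis. Within each group
the predictor is centred at the group mean, which leaves the
interaction coefficient unchanged and defines main effects at the
group means.

## Synthetic cohorts

`generate_cohort` draws exogenous latents from a specified covariance,
builds lesion load from a truncated log-normal on the percent-of-TIV
scale, forms the cognition latents with linear lesion and connectivity
effects plus the product term `omega * (w - mean(w)) * xi` and
unit-variance disturbances, emits indicators as loading-weighted latent
sums plus Gaussian residuals (jointly drawn for residual-covariance
blocks), and injects missingness last. Every random component draws
from its own stream keyed by `(seed, crc32(name))`, so identical seeds
give byte-identical tables and extending a configuration does not
perturb existing columns.

Default study conditions (`study_cohort_config`): n = 230 with 140 HO
and 90 MCI; ten cognition indicators with the nested structure above
(speed tests loading negatively until inverted); six fronto-parietal,
three salience, and six default-mode Fisher-z indicators with
standardized loadings in the 0.5-0.8 range; a reserve factor coupled
to the control networks; lesion load matching a mean of 0.17, SD 0.37,
range 0-2.8 percent of TIV overall with group means near 0.11 (HO) and
0.28 (MCI); a negative lesion effect on all cognition factors
(strongest for executive function), a positive lesion x fronto-parietal
interaction on executive function only, and a vascular-risk score
acting on lesion load and cognition. Group shifts are mean shifts on
the latents and the lesion log-scale, of sizes chosen to produce
clearly significant group differences; the exact published factor-score
gaps are not uniquely recoverable, so these are emulation choices.
Missingness reproduces the reported counts exactly: 91/230 lifestyle
entries (MCAR) and one lesion value (in an MCI participant). Lesion
load is exposed both raw and log1p-transformed; analyses default to the
raw percent scale, which is what makes unstandardized moderation
coefficients of magnitude ~2-4 per percent TIV interpretable.

What the generator does *not* emulate: voxelwise fMRI or FLAIR data
(lesion masks are handled separately and only volumes enter the
models), non-Gaussian indicator residuals, floor/ceiling effects in
test scores, site effects, and any misfit of the factor structure
itself — generated data satisfy the fitted model family exactly except
for the lesion distribution's non-normality. Passing recovery tests
therefore demonstrates correctness of the estimators under the study's
design and realistic effect sizes, not robustness to structural
misspecification.

## Simulation sizes and numerical tolerances

The validation suite uses the following problem sizes, chosen to keep
Monte-Carlo error well below the widths of the acceptance bands while
the full suite stays comfortably runnable on one CPU: moment fidelity
at n = 50,000; loading recovery at n = 10,000; interaction recovery
and CI coverage over 100 cohorts of n = 2000; interaction type-I error
over 500 null cohorts of n = 230; likelihood-ratio calibration over
500 cohorts of n = 200; multigroup power/specificity over 100 cohorts
of n = 500 per group. Reduction identities (observed-product
equivalence, one-group multigroup, FIML-equals-ML) are asserted at
1e-6; enumeration oracles (casewise likelihood, Cook's distance) at
1e-10; the quadrature doubling diagnostic at 1e-3.

## Known limitations

* Only one latent may enter the product term (observed x latent and
  observed x observed); latent x latent products of two multi-indicator
  latents are out of scope.
* No categorical/ordinal indicators, no robust (sandwich) corrections,
  no weighted least squares.
* The latent-moderator fit conditions on exogenous observed variables;
  subjects missing the predictor are dropped rather than integrated
  over.
* Multigroup fits force equal latent means under the default
  constraint set (see above).
* Lesion frequency maps assume masks already share a common reference
  grid; no resampling or warping is performed.
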