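# Methods

## The disease axis

Huntington's disease is caused by a CAG trinucleotide expansion in *HTT*;
longer repeats cause earlier onset. The CAG-Age Product,

    CAP = age × (CAG − L),        L = 33.66 (default),

combines repeat length and exposure time into a single cross-sectional
disease-burden axis, letting carriers with different repeat lengths be
analysed together. `L` approximates the pathogenic threshold and is a
configuration value (`CapConfig.threshold_l`), never hard-coded.

Controls have no meaningful CAP. Because regional volumes in carriers far
from onset are essentially indistinguishable from controls, controls can
stand in for the far-from-onset (flat) part of the trajectory. Two
surrogate schemes are first-class:

* **multiplier** (default): control CAP = age × `control_multiplier`. The
  default multiplier of 5.6 places a control cohort of mean age ~45 at a
  mean surrogate CAP of ~253, spreading controls over the low-CAP range
  while staying left of every plausible changepoint. It is deliberately
  arbitrary and user-overridable.
* **age identity**: control CAP = age.
* **exclude**: carriers-only analyses, controls dropped.

Under either surrogate scheme, only controls younger than
`control_age_cap` (default 40 years) are admitted, since only young
controls are credible stand-ins for far-from-onset carriers. The filter is
applied at CAP-assignment time so carriers-only analyses are untouched.

## The trajectory model

For one region's response `y` (raw volume in mm³, or the dimensionless
ratio volume/whole-brain when normalizing) the mean model is

    y = v0 − δ·S(max(c − τ, 0)/s) + study offsets + group offsets
        + β_ICV·(ICV − mean ICV) + ε,

with `c` the CAP score, `S(u) = 2/(1+e^(−u)) − 1 = tanh(u/2)`. The curve
is **exactly** flat at `v0` left of the changepoint `τ`, continuous at
`τ`, monotone non-increasing, and approaches `v0 − δ` as CAP grows. The
exact sigmoidal form is a modelling choice: this half-logistic ramp was
picked because it is the simplest form that is genuinely flat on the left
(matching the far-from-onset approximation), sigmoidal on the right, and
linear-in-parameters once `(τ, s)` are fixed. It lives in one pure
function (`trajectory.left_flat_sigmoid`) so an alternative (e.g. a full
logistic with a free left asymptote) is a one-function swap.

`δ ≥ 0` is enforced: atrophy is monotone, and a region that does not
decline degenerates cleanly to the constant model. Covariates (study
batch, clinical group, mean-centred ICV) enter additively with
reference coding (alphabetically first level fixed at zero). Whole-brain
normalized analyses keep ICV as a covariate by default (`include_icv`
switches it off).

### Fitting

Least squares by changepoint profiling. Conditional on `(τ, s)` the model
is linear in `(v0, δ, covariates)`, so the fitter:

1. sweeps `τ` over a fixed grid — multiples of `tau_grid_step` (default 5
   CAP units) spanning the 5th–95th percentile of observed CAP;
2. for each `τ`, evaluates a coarse geometric grid of widths `s` within
   `scale_bounds` (default: half a grid step up to the observed CAP span)
   using a precomputed projection of the ramp regressors onto the
   orthogonal complement of the covariate block (one matrix–vector
   product per response vector);
3. polishes the best few candidates with a bounded Brent search on `s`;
4. solves the final linear problem, clamping `δ` to 0 if the unconstrained
   drop is negative.

Ties on RSS break toward the smaller changepoint. The fit is flagged
non-converged when the optimum sits on the τ-grid boundary or `δ = 0`
(no detectable changepoint). The optimizer is deterministic — grid,
bounded 1-D search and linear algebra only — so identical inputs give
bit-identical fits. A naive brute-force reference
(`validation.brute_force_profile_rss`) cross-checks the projection
shortcut to 1e-6 relative RSS.

Scans are treated as independent observations at fit time; within-subject
correlation is honoured at inference time by the subject-block bootstrap.

### Model comparison

Constant ⊂ linear and constant ⊂ sigmoid are exact nestings. The
improvement statistic for sigmoid over linear is F-like,

    stat = (RSS_lin − RSS_sig)/RSS_sig × (n − p_sig)/(p_sig − p_lin),

but because `τ` is estimated its null distribution is not F; p-values come
from the bootstrap. With `δ ≥ 0` the sigmoid family contains declining
lines only in a limiting sense, so `RSS_lin ≥ RSS_sig` is guaranteed in
the declining-trajectory regime the model targets, not for arbitrary
(e.g. upward-trending) data — there the constrained sigmoid degenerates to
the constant fit. The validation suite therefore exercises the nested RSS
ordering on cohorts drawn from the declining flat-then-sigmoid family
(drop at least ~3 noise SDs). Without a bootstrap p-value, preference
falls back to BIC (error-variance form, counting `τ` and `s` as
parameters).

## Bootstrap inference

Semi-parametric is read as: parametric fitted mean + non-parametrically
resampled residuals. Residuals move in subject blocks — a subject's whole
residual vector is replaced by that of a uniformly drawn subject with the
same number of scans (donor groups by visit count keep vector lengths
aligned). `resample_unit="scan"` gives the plain residual bootstrap.

* **Changepoint SD**: resample around the sigmoid fit, refit, take the
  sample SD of replicate `τ` estimates. Non-converged replicates are
  dropped and counted; more than 20% dropped flags the result unstable.
* **Sigmoid-vs-linear p-value**: null datasets are the fitted *linear*
  mean plus resampled linear residuals (constant null available via
  config); the observed statistic is referred to the null distribution
  with the add-one convention `p = (r+1)/(B+1)`, so `p ∈ [1/(B+1), 1]`.
  Boundary replicate fits are kept here — they still yield a valid RSS,
  and dropping them would truncate the null.

Defaults: 999 replicates, subject-level resampling, linear null. All
resampling is driven by one seeded generator; results are bit-reproducible
given (data, options).

No multiplicity correction is applied across regions by default (results
are reported per region); `changepoint.bh_adjust` provides optional
Benjamini–Hochberg control.

## The synthetic cohort generator

The generator emulates the merged multi-study table the analysis expects:

* three study arms with weights 0.12/0.35/0.53 and batch offsets of
  0–2% of each region's flat level; group offsets likewise fractional
  (offsets are scale-free fractions of `v0` so one scenario covers regions
  from ~600 to ~140,000 mm³);
* control CAG ~ N(20.4, 3.5) clipped to [15, 31]; carrier CAG
  ~ N(42.7, 2.4) clipped to [38, 55]; baseline age uniform on [18, 72];
  1–5 visits ~1 year apart with 0.85 per-visit retention;
* per-subject ICV ~ N(1.5e6, 1.2e5) mm³, coupled to volumes at 0.4·v0 per
  relative head-size unit;
* carrier volumes follow each region's true left-flat sigmoid at the
  subject's true CAP; controls are generated disease-free at the flat
  level (their surrogate CAP is assigned downstream, exactly as for real
  data); whole-brain volume has its own sigmoid truth (9% drop, τ = 370)
  so normalized analyses show relative sparing as rising ratios;
* homoscedastic Gaussian noise per region, SD = 3% of `v0` by default
  (Student-t(4) under `heavy_tails`); artefact flags at rate 2% feed the
  QC exclusion path; clinical scores (TMS, SDMT, TFC, BDI) are generated
  as crude monotone functions of CAP and carried as passthrough columns.

The default region truths stagger changepoints with the basal ganglia
(putamen τ = 250 … substantia nigra τ = 320) earlier and steeper than
cortex/white matter (τ = 340–460) and cerebellum/hippocampus nearly
spared. These truths are synthetic package fixtures chosen for
qualitative realism, not estimates from any cohort.

What the generator does **not** emulate: segmentation error structure
(spatially correlated, region-size dependent), scanner/protocol drift
within study, informative dropout, within-subject residual correlation
beyond the shared subject trajectory, and measurement floor effects in
small structures. Passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to every
artefact of real imaging data.

## Validation studies and problem sizes

`captraj.validation` fixes the study conditions used by the test suite and
the reproduction script:

* zero-noise identifiability: 280 subjects, exact recovery to 1e-6;
* brute-force agreement on a ~50-scan dataset, 1e-6 relative RSS;
* recovery: 300 carriers + 100 controls, 3% noise, true τ = 300, 20
  replicates (median |τ̂ − τ| well under the 5-unit grid resolution ×3);
* type-I: 200 carriers-only linear-truth datasets, 199 bootstrap
  replicates each;
* coverage of τ̂ ± 2·SD: 100 replicates at 150 carriers + 60 controls;
* ordering: six regions staggered by 50 CAP units, 20 replicates, and the
  basal-ganglia-first check on the default scenario.

These sizes were chosen so each study is informative at desk scale while
the whole suite stays fast; all are parameters of the study functions.

## Numerical choices and degenerate inputs

* τ grid snapped to multiples of the step so stated changepoints can lie
  exactly on the grid; a CAP span narrower than one step is an error.
* Ramp columns that project to (numerically) zero — τ at the far right of
  the data — contribute the covariates-only RSS.
* Collinear covariate designs raise with the offending column names;
  factors with one observed level simply contribute no columns.
* `rss = 0` (interpolating fits) maps AIC/BIC to −∞ rather than erroring.
* Responses are never log-transformed by default (`log_response` exists).

## Known limitations

* The changepoint estimate is grid-quantized (default 5 CAP units); its
  bootstrap SD inherits that granularity and can collapse to zero when the
  signal is very strong. Coverage was verified at the default conditions.
* With `δ ≥ 0`, data trending upward (relative sparing in normalized
  analyses) are fit as flat; modelling recovery/increase is out of scope.
* No random-effects estimation: subject correlation is handled only at
  inference time by block resampling.
* Small control arms can leave group levels with few observations in
  carrier-heavy analyses; reference coding still works but offsets are
  then weakly identified.
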