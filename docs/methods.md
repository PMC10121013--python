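# Methods

## The model

`springlayer` treats the soft tissue of a musculoskeletal extremity site as
fat and muscle layers stacked between the skin and the bone, idealized as two
linear (Hookean) springs in series. For springs in series compliances add, and
each layer's spring constant is `E·A / t` (modulus × loaded area / thickness),
so with a probe of constant contact area `A` the aggregate surface compliance
of an indentation trial is

    A/k = t_m / E_m + t_f / E_f

where `k` is the slope of the pressure–displacement line of the trial, `t_m`
and `t_f` are the unloaded muscle and fat thicknesses (mm), and `E_m`, `E_f`
are effective layer moduli. Regressing measured compliance (mm³/N) on the two
thicknesses **without an intercept** therefore yields coefficients that are
the layer *inverse moduli* `1/E_m`, `1/E_f` in mm²/N (numerically equal to
1/MPa). The zero intercept is part of the physics: zero thickness must mean
zero compliance. A conventional variant with a free intercept is fitted as a
sensitivity check; its coefficients no longer have a modulus interpretation.

Two scopes are supported:

* **location-specific** — ordinary least squares within one of the eight
  sites (lower/upper × arm/leg × anterior/posterior);
* **combined** — all sites pooled, with crossed zero-mean random intercepts
  for subject and for site:

      y_ij = x_ij' β + u_i + v_j + ε_ij,
      u_i ~ N(0, σ²_subject), v_j ~ N(0, σ²_location), ε ~ N(0, σ²_resid)

Given inverse moduli and the trial's maximum force, the serial-spring model
also predicts each layer's deformation:

    Δt_m = (t_m / E_m) · F_max / A,    Δt_f = (t_f / E_f) · F_max / A

These sum, exactly, to `F_max/A` times the fixed-effect-predicted compliance —
the series decomposition identity, which the test suite asserts at 1e-12.

## Estimation

Location-specific fits are least squares with residual-variance standard
errors (df = n − p) and two-sided t p-values. Combined fits are REML: the
restricted log-likelihood is profiled over the fixed effects (GLS) and the
residual variance, leaving a two-dimensional optimization over the log
variance ratios `σ²_subject/σ²_resid` and `σ²_location/σ²_resid`, run with
Nelder–Mead from three starts (ratios ≈ 1, ≈ 1e-3, ≈ 10) to be robust at the
zero-variance boundary; ratios below 1e-8 are reported as exactly zero with a
boundary warning. Because the random-effect covariance is low-rank, the
likelihood, GLS solution and BLUPs are evaluated through the Woodbury
identity on the stacked indicator design — cost is cubic in the number of
random-effect levels (~108 for a full study), not in the number of trials —
so a full-study fit takes well under a second. The public
`reml_objective(variance_components, X, Z_subject, Z_location, y)` evaluates
the same restricted likelihood at arbitrary non-negative components, which is
what the brute-force grid tests call.

Fixed-effect standard errors are the GLS plug-in `(X' V̂⁻¹ X)⁻¹` and p-values
are Wald-normal. This conditions on the estimated variance components; with
only eight location levels the resulting intervals are mildly anticonservative
(simulation under the model puts ±2·SE coverage near 93–95% rather than the
nominal 95.4%). Degrees-of-freedom corrections in the Satterthwaite or
Kenward–Roger family are deliberately out of scope.

Prediction from a combined fit is either `fixed_only` (Xβ) or `conditional`
(Xβ plus the subject and location BLUPs, `γ Z' W⁻¹ (y − Xβ̂)`; unseen levels
get zero). Conditional prediction is the default when comparing against the
location-specific models, because the combined model's advantage is precisely
that it can express subject-level offsets. Layer-deformation prediction always
uses fixed-effect coefficients only: the random intercepts are compliance
offsets with no principled attribution to an individual layer.

## The synthetic-data generator

The generator inverts the analysis: it draws a study from the combined
physics model and then renders the raw channels the pipeline consumes.

* **Thicknesses** — per-site truncated normals (truncated at zero). Site
  means span fat 6–18 mm and muscle 20–45 mm, with muscle clustering by site
  more strongly than fat, giving site-mean compliances of roughly 200–500
  mm³/N under the default inverse moduli.
* **True compliance** — assembled exactly as
  `inv_E_m·t_m + inv_E_f·t_f + u_subject + v_location + ε`, with default
  inverse moduli 3.77 and 18.10 mm²/N (magnitude-realistic for muscle and
  fat; fat about five times more compliant). Draws with non-positive
  compliance are resampled up to 100 times and then error out rather than
  being silently clipped.
* **Noise SDs** — defaults σ_subject = 30, σ_location = 20, σ_resid = 30
  mm³/N. These are sized by a self-consistency constraint, not fitted to any
  dataset: the additive-Gaussian model is only coherent if compliance is
  effectively always positive, so the combined noise SD is kept small enough
  that P(compliance ≤ 0) < 1e-4 at the thinnest site (mean ≈ 200 mm³/N).
  Real studies show proportionally larger scatter; this generator is
  deliberately under-dispersed plumbing for parameter-recovery testing, not
  an estimate of any population.
* **Force–displacement trace** — linear with slope `A/compliance`, plus
  gaussian force noise (default SD 0.1 N), force pinned to zero at zero
  displacement. The indentation depth is `max_displacement` (default 5 mm)
  but is capped per trial so no layer exceeds ~60% compression — the
  serial-spring split makes a layer's strain `inv_E · depth / compliance`,
  so very compliant trials are indented less, as an operator would.
* **Boundary traces** — probe-face offset and skin thickness are constant
  (the skin layer carries no mechanics); the fat/muscle and muscle/bone
  boundaries move with the *noisy* force channel so that the deformation
  extracted at the max-force sample equals the serial-spring value plus the
  trial's deformation-noise draw (default SD 0.2 mm) exactly. Slightly
  negative apparent deformations are generated (annotation noise) and
  clamped to zero at extraction, with a logged warning. Probe displacement
  and boundary kinematics are separate channels; the pipeline never
  cross-checks them, and the skin/residual remainder of the bulk
  displacement is implicitly absorbed above the fat layer.
* **Determinism** — one root seed; the effect draws and each trial's
  substream are derived from `(seed, subject index, site index)`, so studies
  are byte-identical across runs and reproducible trial by trial.

What the generator does **not** emulate: ultrasound imaging or boundary
annotation itself, nonlinear/viscoelastic response (the trace is exactly
linear), skin mechanics, heteroscedastic or skewed compliance scatter,
missing data beyond what the exclusion logic is tested with. Passing
recovery tests therefore show the pipeline is correct *under its own
assumptions*; they do not certify accuracy on real indentation data.

## Feature extraction

Per trial: force is re-baselined to zero at the zero-displacement sample;
pressure is force / probe area; surface stiffness is the least-squares slope
through the origin, `Σ(d·p)/Σ(d²)`; compliance is its reciprocal. Initial
thicknesses come from the first-sample boundary depths; experimental layer
deformations are initial minus at-max-force layer thickness, clamped at zero
with a warning if slightly negative. Trials with a non-positive fitted slope
(e.g. a dead force channel) are excluded with a logged reason rather than
erroring, and the feature table carries the exclusion count so that
rows out + exclusions = trials in. The deformation readout frame is the
max-force sample (configurable in principle; max force is what enters the
deformation formula, so it is the consistent choice).

## Evaluation conventions

* Prediction error: absolute percent difference `100·|pred − exp| / exp`
  (the experimental value is the reference). A symmetric mean-normalized
  mode `100·|pred − exp| / ((pred+exp)/2)` is available separately.
* Coefficient comparisons between two fits use the mean-normalized form —
  with the published combined-model coefficient pairs it reproduces the
  reported 13.29% (muscle) and 2.17% (fat) differences within rounding.
* Summaries are mean ± sample SD (n−1).
* The recovery study re-runs simulate → extract → fit over seeded
  replicates and reports per-parameter bias and empirical coverage of
  ±2·SE. Coverage adds a 1e-9·|truth| absolute slack so the interval stays
  meaningful when all noise is zero and the SE underflows; replicate
  failures (including generation errors from pathological configs) are
  recorded and tolerated up to 20%.

## Problem sizes used in the shipped tests and acceptance script

Unit and property tests run on 12-subject × 4-site studies with short
traces. The recovery check uses 400 replicates of the full default study
(100 subjects × 8 sites) — enough that the binomial error of the empirical
coverage estimate (~1.2 points) is small against the margin between the
interval's actual coverage (~94–95%) and the 90% requirement; the
combined-vs-location-specific comparison uses
20 replicates at 30 subjects × 8 sites; the REML grid-search oracle uses
6-subject × 3-site instances where dense-matrix brute force is cheap. These
sizes are the package's own test design: large enough for stable
Monte-Carlo estimates, small enough to run routinely.

## Known limitations

* Wald-normal inference for mixed-model fixed effects (see above); p-values
  for the location variance-adjacent contrasts are approximate.
* The generator's additive constant-SD random effects are a simplification;
  real compliance scatter scales with its mean.
* The linear serial-spring model under-predicts stiffness at large
  deformations by construction; no nonlinear correction is attempted.
* The skin layer is ignored throughout, consistent with its near-zero
  recorded displacement in the motivating measurements.
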