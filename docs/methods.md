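# Methods

`pupilgca` implements, as a tested and reusable pipeline, the full
pupillometric and behavioral analysis of a semantic relatedness
judgement experiment: a synthetic task-evoked-pupillary-response (TEPR)
generator with known ground truth, the multi-stage pupil preprocessing
procedure, growth curve analysis (GCA) with third-order orthogonal
polynomials, and the behavioral mixed-model analysis with BIC Bayes
factors.  This note documents the models, their assumptions, the
defaults, and the design choices that were genuinely open.

## The experiment being emulated

Participants judge whether word pairs are related.  The design crosses
semantic relation **type** (taxonomic — shared features, *dog–wolf* —
vs. thematic — event co-occurrence, *dog–leash*) with relatedness
**strength** (high vs. low), 16 pairs per cell, plus 64 unrelated
fillers: 128 trials per participant, 60 participants.  Each trial shows
a fixation cross for 1000 ms, then the word pair until response.  Pupil
diameter is recorded monocularly at 250 Hz; cognitive effort produces a
transient dilation time-locked to the judgement.

Word pairs carry taxonomic-similarity and thematic-relatedness ratings
on a 1–7 scale and are assigned to cells by fixed windows: high-strength
pairs have a rating difference > 1.75 with the non-dominant relation
≤ 3.5; low-strength pairs have a dominant rating ≤ 4.5 and a difference
in [0.5, 1.75].  `classify_pair` implements exactly these windows; the
stimulus generator rejection-samples ratings (per-cell normal
distributions matched to the published stimulus norms) until every cell
is filled with conforming pairs.

### Contrast coding

Both factors are sum-coded: **taxonomic = +1, thematic = −1; high = +1,
low = −1**, and the interaction code is their product.  The source
study does not report its level ordering, so coefficient *signs* here
follow this package's convention; the generator's effect directions are
chosen so the documented phenomena hold (taxonomic slower and
steeper-dilating than thematic; low strength slower, less accurate, with
a steeper and longer-lasting dilation; low-taxonomic the most
sustained).  Magnitudes are the published estimates.

## Synthetic data generator

### Pupil trajectories

The generating dilation trajectory is parameterized **directly on the
analysis basis**: an orthonormal third-order polynomial basis on the 21
bin midpoints (100, 300, …, 4100 ms).  A trial in condition *c* with
sum codes (t, s) has noiseless truth

    y(τ) = baseline + [1, P(τ)] · (β₀ + t·βт + s·βѕ + ts·βтѕ + b)
           + t·b_t + s·b_s + ts·b_ts,   τ ≥ 0,

where each β is a 4-vector over (intercept, linear, quadratic, cubic),
`b` collects the participant's random time-course effects, and the
trailing terms are the participant's condition-shift random effects —
the exact random structure of the fitted GCA model, which makes
parameter recovery well-posed by construction.  P(τ) is the polynomial
interpolant of the bin-midpoint basis.  During fixation the truth holds
the participant's baseline (default 4.5 ± 0.4 mm across participants);
because pupil size is physically continuous, the last 200 ms of
fixation ramp linearly into the trajectory's onset value
(`onset_ramp_ms`).

Default generating coefficients (mm on the unit-norm basis) are the
published pupillary effect estimates, e.g. overall
(0.06, 0.12, −0.07, 0.01), strength (0, −0.019, −0.014, 0.004),
type (0, ±0.01, …) and interaction (0, ∓0.018, ∓0.018, 0) with signs
per the coding convention above.  A gamma-impulse physiological kernel
was considered as an alternative trajectory family and rejected: it
would decouple the generator from the analysis basis and make "truth"
for the polynomial coefficients ill-defined.

Per-participant random-effect SDs are not published; they were set once
from the published SEs (≈ SE·√60): intercept 0.08, linear 0.23,
quadratic 0.15, cubic 0.12, condition shifts 0.05 mm.

### Noise

Two components (`Ar1Noise`):

* **AR(1) sample noise** — stationary, ρ = 0.99 per 4 ms sample,
  marginal SD 0.05 mm: the strongly autocorrelated sensor/physiology
  noise seen in raw pupil traces.
* **Trial-level trajectory variability** (`trial_sd_mm`, default
  0.35 mm) — each trial's response deviates from the participant's mean
  trajectory by an independent draw per 200 ms bin, interpolated to the
  sample grid (and ramped in at onset like the trajectory itself).
  This is the component that dominates the standard errors of the
  polynomial-by-condition terms in real TEPR data; its default was
  calibrated so that the simulated model SEs at 60 participants
  reproduce the published SE magnitudes (~0.006–0.01 mm).  AR(1) noise
  alone cannot play this role: it leaves bin-level residuals so strongly
  autocorrelated that the mixed model's iid-residual SEs are several
  times too small.

  *Idealisation to note:* drawing trial variability independently per
  bin makes the analysis model's iid-residual assumption true in the
  simulated world, so recovery and calibration results here certify the
  pipeline's correctness, not the iid assumption itself.  Real pupil
  residuals are smoother, and GCA SEs on real data are accordingly
  somewhat anti-conservative — a known property of the method.

### Artifacts

`inject_artifacts` adds, on top of the observed series and never
touching the stored truth: blinks (Poisson onsets, default 0.2/s,
uniform 100–300 ms durations; samples flagged invalid and read as
missing, as tracker exports do), spikes (isolated valid samples offset
±1 mm, default 0.5/s — these are *not* flagged, the filters must find
them), and dropout (independent invalid samples, default probability
0.002).  An injection log (blink runs, spike indices) is retained so
tests can audit filter accounting.

### Behavior

Reaction times are shifted lognormal:
`rt = 200 + exp(7.0 + participant + item + shifts + ε)` ms
(ε SD 0.25; participant SD 0.15; item SD 0.08 on the log scale), with
condition shifts on the log scale sized so the implied contrasts on the
analysis scale −1000/rt match the published effects (|type| ≈ 0.040,
|strength| ≈ 0.048).  Because the shifts act on log RT, the implied
truth on the −1000/rt scale has no closed form;
`behavior_truth_neg_inv_rt` evaluates it by Monte Carlo for recovery
tests.  Accuracy is Bernoulli-logistic with intercept 2.2 (≈ 90%
correct, matching the reported 10% error rate), condition logits
(±0.202 type, 0.422 strength), participant SD 0.5 and item SD 0.4;
fillers use a separate intercept (2.6).

### Determinism

`simulate_dataset(spec)` derives all randomness from `spec.seed` through
a seed sequence that spawns independent child streams for the stimulus
set, the item effects, and each participant, so any subset of
participants is reproducible in isolation and identical spec + seed
gives byte-identical output.

## Preprocessing

Stages in fixed order, each with the published constant as its default:

1. arbitrary units → mm.  No conversion formula is published; the
   default is division by a calibration scale (1000 au/mm, diameter
   mode); area-mode trackers are supported via
   `mm = 2·sqrt(au/(scale·π))`.
2. missing-data exclusion, strictly greater than 30%: participants
   first (fraction of all their samples), then trials.  Computing the
   participant fraction over post-exclusion trials would make the rule
   vacuous — with the trial rule applied first, every retained trial is
   ≤ 30% missing, so their weighted mean cannot exceed 30% — hence the
   all-samples definition.
3. implausible samples: outside 2–8 mm removed first, then samples
   beyond the trial's mean ± 3 SD (mean and SD from the remaining valid
   samples of that trial).
4. blink handling: every maximal invalid run widened by 100 ms per side,
   then linear interpolation between the nearest valid anchors.  Edge
   runs with only one anchor are filled by nearest-value extension
   (interpolation needs two anchors; dropping such trials would
   over-exclude).
5. dilation-speed artifact rejection: per-sample speed
   d[i] = max(|Δp|/Δt backward, forward); threshold
   median(d) + 16·MAD(d); strictly-greater comparison (so a constant
   trial, where MAD = 0, loses nothing); removed samples re-interpolated
   so downstream stages see gap-free series.
6. 5-point centered moving average, window shrinking at the edges (no
   phantom zeros that would bias edges toward zero).
7. subtractive baseline correction: median pupil over [−500, 0) ms.
8. binning: [0, 4200) ms in 21 left-closed 200 ms bins, bin value =
   mean of its samples (median available); bins with no samples are
   absent, never zero-filled.

Every sample carries a provenance flag (observed / interpolated /
removed-range / removed-sd / removed-mad) and the `ExclusionReport`
aggregates counts per rule, so simulated injections can be audited
against removals.

**Exactness contract.** On noise-free, artifact-free input the pipeline
must reproduce the generator's truth bins exactly.  Two facts shape how
that is stated: a centered moving average is not the identity on curved
data (≈ 1e-6 mm bias here), so the generator's truth-bin table
(`binned_truth`) applies the same deterministic smoothing operator to
the noiseless signal before binning; and the 3 SD filter genuinely
clips the trajectory peaks of steep-random-slope participants even on
clean data (a long constant fixation epoch concentrates the sample
distribution), so the exactness check uses the fully degenerate
generator — zero noise *and* zero random-effect variance — where every
filter is provably a no-op.  With artifacts injected (and noise off),
filter accuracy is instead quantified as binned RMSE versus truth
(< 0.02 mm under the default rates).

An open question in the source procedure is whether trials with
incorrect behavioral responses entered the pupil analysis; the pipeline
includes all analyzable trials by default, and accuracy-based filtering
belongs to the behavioral screening stage.

## Growth curve analysis

`GrowthCurveModel` fits

    pupil ~ (poly1 + poly2 + poly3) * type * strength
            + ((poly1 + poly2 + poly3) + type * strength | participant)

by REML (statsmodels `MixedLM`), where poly1–3 are the unit-norm
orthogonal polynomials on the bin midpoints (QR orthogonalization of the
Vandermonde matrix, signs fixed positive on the matching raw power —
the convention of R's `poly`).  Coefficient magnitudes depend on the
basis normalization; unit-norm columns are asserted in tests.  Binned
trials are aggregated to participant × condition × bin means before
fitting (the random structure is by participant, so trial replicates
add rows, not information, and aggregation keeps the fit fast and well
conditioned).

The intercept is the average dilation over the window; the linear term
the overall slope; the quadratic the primary curvature (more negative =
steeper inverted-U); the cubic a secondary inflection.  Each condition
column tests how that shape component differs across the design.

**Fallback ladder.** If the maximal (full-covariance) structure fails
to converge the fitter refits with independent variance components per
random term, then with random intercepts only, recording the rung in
the result; a fit that fails every rung is returned flagged, never
silently.  For crossed designs (the RT model: by-participant slopes
plus by-item intercepts) statsmodels supports only the
variance-component formulation in a single grand group, so the ladder
starts at the diagonal rung there; this estimates independent
random-effect variances rather than a full covariance — the estimation
scheme of this package, documented here and in the fit metadata.

**Inference.** Test statistics use the normal (z) approximation
(Satterthwaite degrees of freedom are not available for this backend);
with 60 participants and thousands of observations the difference is
small, and recovery checks use estimates and SEs, not p-values.  Main
effects with predeclared directions get one-tailed p-values
(p_two/2 when the sign matches, 1 − p_two/2 otherwise); interactions
stay two-tailed.  The report grid (`gca_table`) is the 4 × 4 layout of
"estimate (SE)" cells with markers at p < 0.001/0.01/0.05.

BIC is −2·logLik + k·log(n) with k counting fixed effects, covariance
parameters, and the residual variance; likelihood-based comparisons
always use ML refits, never REML.

## Behavioral analysis

Screening (all strict inequalities, in order): participants below 75%
correct are excluded (the study *replaced* them — a data-collection
act; the pipeline excludes and reports, and the simulator can top up N);
items below 60% accuracy are discarded; for the latency analysis only,
error trials and correct RTs < 250 ms are dropped.  The accuracy
analysis keeps error trials.  Both models use experimental (non-filler)
trials by default.

The RT model is `−1000/rt ~ type * strength` with by-participant
slopes for both factors and their interaction and crossed by-item
intercepts.  The inverse transform normalizes latency skew while
preserving order.  After the initial fit, observations with
standardized *marginal* residuals (response minus fixed-effect
prediction, scaled by their own SD) beyond 3 SD are removed and the
model refitted once — single-pass by design.

The accuracy model is a logistic GLMM, `accuracy ~ type * strength`
with by-participant intercepts and type slopes plus by-item intercepts
(the reduced structure the study settled on after non-convergence).  No
maximum-likelihood GLMM exists in the scientific Python stack, so the
package implements one: penalized IRLS for the joint (β, u) mode,
Laplace approximation for the marginal likelihood, Nelder-Mead (with
restarts) over the log-SD variance parameters.  Profiling β inside the
inner step makes this exactly lme4's `glmer(nAGQ = 0)` algorithm — a
test reproduces that fit to numerical precision — restricted to
diagonal random-effect covariance.  Complete separation (constant
response) raises a dedicated error; quasi-separation is flagged in the
fit notes.

Model comparisons use the BIC approximation to the Bayes factor,
`BF_ab = exp((BIC_b − BIC_a)/2)`, from ML fits on identical data; for
the RT interaction question the reduced model drops only the
`type:strength` fixed term and keeps the random structure.

## Simulation-study problem sizes

Parameter recovery for the GCA uses 60 simulated participants at the
published trial counts with 25 replicates, generated through the
bin-level fast path (`simulate_binned_means`: same trajectory, random
effects, and noise model as the sample-level generator, aggregated
analytically to the fitting grid — full sample streams add nothing for
replicated model fits).  Pooled 2-SE coverage across the 16 fixed
effects is the headline figure; per-term coverage at 25 replicates has
binomial noise of ± ~9 percentage points, which is why the per-term
check uses a floor rather than the pooled threshold.  Behavioral
null calibration uses 12 participants × 8 items/cell and 100–200
replicates; type-I rates are assessed against the binomial 99% interval
around 1%.

## Known limitations

* Trials are simulated at full display length; response-terminated
  truncation of the pupil stream is not emulated (the binning stage
  handles truncated trials, covered by unit tests on constructed data).
* No gaze-position or luminance confounds, saccades, or fixation events
  are simulated, and the pipeline performs no gaze/luminance
  regression.
* The crossed-design mixed models estimate independent random-effect
  variances (no slope-intercept correlations).
* GLMM estimation is the nAGQ = 0 Laplace flavour; estimates can differ
  from adaptive-quadrature fits by a fraction of an SE at small n.
* The simulator's bin-independent trial variability and polynomial
  trajectory family are idealisations; passing recovery tests certify
  the pipeline, not those assumptions, on real data.
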