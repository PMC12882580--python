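# Methods

This note documents the models, estimators and design choices behind
`tracekin`, and what its synthetic data can and cannot show.

## Target shapes

The four task shapes belong to the pure-frequency family: log-curvature is
a sinusoid in angular displacement, κ(θ) = κ₀·exp(ε·sin(νθ)), with angular
frequency ν = p/q in lowest terms (clover 4/5, petals 4/3, ellipse 2,
rounded square 4). Position is integrated from the heading ODE
dx/dθ = cos θ/κ, dy/dθ = sin θ/κ with fixed-step RK4 at 2048 steps per 2π
over θ ∈ [0, 2πq]. For these ν the curve closes exactly in the continuum
(the Fourier expansion of 1/κ contains no mode at frequency 1 when p does
not divide q), so the only closure error is RK4 truncation; it is removed
by subtracting the endpoint drift linearly in θ, and the residual gap is
checked against 10⁻⁶ of the perimeter. The curve is then scaled uniformly
so its larger bounding-box dimension equals `max_dim_px` (default 9 cm at
the tablet's 8.83 px/mm; 2000 × 1200 px on a 10.40-inch diagonal) and
anchored with the origin at the bounding-box bottom-left, y up, positive θ
counter-clockwise.

The oscillation amplitudes ε (clover 1.2, petals 1.0, ellipse 0.7, rounded
square 0.8) are configuration keys: the family fixes the oscillation
*count*, and every quantitative claim made by the tests is insensitive to
the amplitude; the defaults simply render recognisable shapes without
inflections.

**Centroid winding.** One subtlety discovered during implementation: a
curve traced with counter-clockwise *heading* need not wind
counter-clockwise about its centroid. The petals shape (ν = 4/3) winds
clockwise — its lobes subtract winding — while the other three wind
counter-clockwise; in all four cases the net position winding per closed
traversal is ±1 even though the heading advances by 2πq. All angular
bookkeeping downstream (trace counting, the ½π initial trim, sub-element
boundaries) therefore uses the *oriented* polar angle: the unwrapped polar
angle about the ideal shape's centroid multiplied by the shape's own
winding sign, so that tracing in the task direction always increases θ and
one completed trace is exactly 2π.

## Synthetic cohort

The generator emulates the study design: three groups (31/32/31
participants), four shapes, two testing days, eight blocks per day (two
per shape, shuffled), up to seven attempts per block until four successes,
ten counter-clockwise cycles per successful trial, a 40-trial reaction-time
task with eight flagged practice trials, and questionnaire scores (AQ,
RAADS, UPDRS-II, PHQ, GAD, non-verbal reasoning) drawn from zero-truncated
normals with the group means and SDs of the cohort summary table; gender
labels reproduce the group counts; age likewise.

Trajectories follow the speed–curvature power law with multiplicative
noise:

    v(s) = c · κ(s)^(−β) · exp(η_slow(s)) · exp(g·z(s))

* β is the group's speed-modulation exponent. Defaults: ASD 0.40, CTRL
  0.33, PD 0.30 — the ASD-elevated ordering on a base near the canonical
  two-thirds-law exponent — with between-participant SD 0.04.
* η_slow is slow log-speed drift (SD 0.08, correlation ≈ 1 s).
* z is band-limited zero-mean noise with ≈ 150 ms correlation time whose
  gain g injects intermittent acceleration sign changes; the downstream
  sub-movement percentage is monotone in g (a tested property). Defaults:
  ASD 0.26, PD/CTRL 0.20. The perturbation acts multiplicatively on speed
  rather than as a literal integrated acceleration process: an integrated
  band-limited acceleration is an unbounded random walk on speed, whereas
  the multiplicative form is stationary and positive with the same
  single-gain interpretation.
* c normalises the time-averaged speed to the group base speed, 500 px/s
  for all groups (the task found no group speed differences, and slower
  speeds would push ten clover cycles past the 90 s trial timeout).
* Spatial imperfection is a low-frequency normal offset (SD 2.5 px,
  correlation ≈ 0.5 s), bounded by the 15%-of-size deviation boundary;
  exceeding it marks the attempt unsuccessful.

Timestamps integrate dt = ds/v, are sampled near 60 Hz with 1 ms Gaussian
jitter, and all randomness flows through one seeded generator: a fixed
seed reproduces the dataset byte-for-byte.

Reaction times are shifted lognormals, RT = shift + LogNormal(μ, σ), with
shifts CTRL 0.45 s / ASD 0.44 s / PD 0.50 s (the PD-slowed, ASD≈CTRL
ordering; magnitudes are calibration, not measurements), μ = log 0.12,
σ = 0.30.

What the generator does **not** emulate: tremor, stylus-lift dynamics,
pressure/tilt, medication state, biomechanics of the arm, or any
questionnaire-kinematics correlation beyond what the group structure
induces. Passing tests therefore demonstrate that the estimators and the
statistical chain behave correctly under the assumed generative model —
not that the real-data effect sizes are reproduced.

## Pre-processing

Per trial, in order: attempts flagged lifted/timed-out are dropped; trials
with fewer than 2.5 completed traces are dropped (trace count computed on
raw samples, before trimming); trials whose speed (raw finite differences)
never reaches 200 px/s within the 5 s grace period are dropped; the first
π/2 of angular displacement is discounted; x(t), y(t) are resampled with a
natural cubic spline onto a uniform 60 Hz grid, after collapsing duplicate
timestamps by averaging. Validation returns enumerated reasons and never
raises; the QC table reports kept/dropped counts per reason.

## Kinematic features

Derivatives use a Savitzky–Golay filter (window 11 samples ≈ 183 ms,
polynomial order 3, both configurable) applied stage-wise: position →
velocity components → acceleration components, speed v = |v⃗|, tangential
acceleration a = dv/dt (signed), jerk j = da/dt, and traced curvature
κ = |vₓa_y − v_y aₓ|/v³. Samples within half a window per differentiation
stage of either end are excluded from aggregation. Trial summaries are
means of v, |a|, |j| (absolute values prevent signed cancellation; the
aggregator choice is ours).

* **Sub-movement %**: sign changes of a between consecutive samples, zeros
  inheriting the previous sign, as a percentage of sample transitions.
  Accelerations below 0.002 × mean speed per second (≈ 1 px/s² here, four
  orders below task-typical accelerations) are treated as zero so that
  interpolation noise on a constant-speed trace scores exactly 0%.
* **Speed modulation β**: Savitzky–Golay-smoothed v and κ, speeds below
  the 1st percentile and curvatures outside [10⁻⁴, 1] px⁻¹ excluded, OLS
  of log v on log κ, β = |slope|; fewer than 50 retained points flags the
  trial unreliable. Noiseless recovery is within 2% of the generating β
  across β ∈ {0.1, 0.2, ⅓, 0.5} on all four shapes (tested at 5%).
* **Min/max speed**: means of the bottom and top ⌈N/10⌉ of log speeds.
* **SPARC**: the trial is split where the oriented traced angle crosses
  the polar angles of the ideal curve's curvature maxima — p identical
  sub-elements per trace; per element, the speed profile is zero-padded
  (next power of two × 4), the magnitude spectrum normalised by its DC
  value, truncated at the adaptive cutoff (last frequency above amplitude
  0.05, capped at 20 Hz — standard published defaults), and the negative
  arc length of the normalised spectrum returned; elements shorter than
  0.25 s are skipped and the rest averaged. Scoring whole trials instead
  of sub-elements gives systematically larger magnitudes (tested), which
  is why the per-element definition is used.
* **Error**: mean |signed normal distance| to the tangent at the nearest
  point of the ideal polyline (KD-tree nearest vertex refined over its
  adjacent segments, ties to smaller arc length).

## Statistics

Per feature, outliers beyond 2 pooled SDs (one grand mean/SD across all
trials, participants and days) are removed and the fraction reported;
speed, acceleration and jerk are log-transformed, minimum speed
reciprocal-transformed; all features are then z-scored. Reaction times are
scored per participant-day as the mean over experimental trials after
within-participant 2 SD outlier removal.

Group matching uses one-way ANOVAs, pairwise Welch t-tests
(Welch–Satterthwaite df) and a gender chi-square; every test is also
available in closed form from (mean, SD, n) summaries, and the
summary-based statistics equal the raw-data statistics to machine
precision (tested).

The mixed models are fitted with statsmodels' `MixedLM` under REML
(Powell optimiser, L-BFGS fallback) with sum-to-zero coding for Group and
Shape. Day and trial-number random intercepts are modelled as variance
components *within* participant — a nested approximation to the fully
crossed random effects, which `MixedLM` cannot express; with only two day
levels and a handful of trial levels the affected variance estimates are
weakly identified either way, and boundary (zero-variance) fits are
accepted. Per-term Type-III F statistics use Wald contrasts on the fixed
effects with containment-style denominator degrees of freedom: terms that
vary only between participants (Group, Age, Depression, Anxiety) are
tested against participant-level df, within-participant terms against
observation-level df. This keeps the group test honestly calibrated —
type-I error 5% ± 3 pp over 200 null replicates in the test suite —
where observation-level df for a between-participant factor would be
anticonservative. Confidence intervals are Wald intervals.

Follow-ups mirror the reporting convention of the analysis reproduced:
when the omnibus Group or Group×Shape term is significant (α = .05,
uncorrected — multiplicity is a known limitation, deliberately not
silently corrected), pairwise two-group models are fitted, and per-shape
two-group models where the pairwise interaction is significant.

Bayes factors for the group effect use the BIC approximation,
BF₀₁ = exp((BIC₊group − BIC₋group)/2), on ML refits of the mixed models
applied to the DV residualised on age, depression and anxiety, tagged
`BIC-approximation`; numeric agreement with JZS-prior Bayesian ANOVAs is
not claimed.

## Classification

Per participant × shape × feature, retained trials are averaged across
trials and days; with reaction time this yields the 37-column kinematic
block (9 features × 4 shapes + RT). Every predictor (including AQ, RAADS,
UPDRS) is residualised by OLS on age, depression and anxiety; missing
participant × shape cells are imputed with the pooled column mean and
logged. Discriminatory features are selected purely from the mixed-model
reports: a significant pairwise main effect admits a feature on all four
shapes, an interaction-only effect admits just the shapes whose per-shape
contrast is significant; the clinical-vs-non-clinical task takes the union
of the ASD-CTRL and PD-CTRL selections and excludes ASD-PD-only
differences.

Each of the eleven feature sets × two tasks is evaluated on one stratified
80/20 participant split (stratification is our interpretation — small
samples make unstratified splits frequently degenerate). KNN's k is tuned
over 1–10 and the random forest's tree count over {100…500} by internal
cross-validation on the training portion; the SVM uses a linear kernel
with C = 1; predictors are standardised on training statistics. A single
80/20 split is seed-dependent by construction; the split seed is recorded
in every result, and repeated-split summaries can be produced by looping
the seed.

## Problem sizes in the test suite

Simulation-based tests use scaled-down cohorts chosen as the package's own
test design: 5/5/5 participants, one day, three cycles per trial for the
end-to-end pipeline; six-cycle single trials for estimator recovery; 200
replicates of 12-participants-per-group tables for mixed-model
calibration; 50 permutation repeats with 15 + 15 participants for
classification chance levels. The full-size default configuration
(31/32/31 × 2 days × 10 cycles) is exercised through the same code paths.

## Known limitations

* The day/trial random effects are nested-in-participant approximations of
  crossed effects (see above).
* The denominator-df rule is containment-style, not Satterthwaite or
  Kenward–Roger; p-values for within-participant terms lean on large
  observation counts.
* The speed-modulation regression inherits the smoothing-parameter
  choices; β estimates are comparable within a configuration, and the
  filter cascade of the original tablet-task literature is not uniquely
  specified.
* SPARC values are comparable only across identical sub-elements; the
  per-element averaging makes cross-shape comparisons approximate.
* Questionnaire scores are independent across instruments within
  participant unless a correlation structure is configured.
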