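# Methods

This note documents the models and procedures implemented in `miniv1`, the
assumptions behind them, the parameters that matter, and the design choices
made where the analysis conventions left the design open.

## Signal model and the synthetic generator

The generator emulates a head-fixed fixation task with brief oriented
stimuli, recorded through an implanted lens with a slow genetically encoded
calcium indicator.

**Task timing.** A trial is fixation onset → stimulus onset 500 ms later →
300-ms Gabor presentation → inter-trial interval drawn uniformly from
4000 ± 1000 ms. Conditions (grid position × orientation) are interleaved in
sequence, so every condition receives exactly the configured repetition
count: 2 repetitions per condition in receptive-field mapping sessions (12
trials per location across the 6 orientations) and 20 trials per orientation
in fixed-position tuning sessions. All trials are successes by default; a
failure-rate knob exists, and failed trials are excluded from every
analysis.

**Cells.** Each ground-truth cell has a 2D Gaussian footprint (σ = 3 px,
unit peak, fully inside the field of view; somata are rejection-sampled to
keep ≥ 6 px apart), a receptive-field grid position, a preferred orientation
θ₀ ∈ [−90°, 90°), a von Mises tuning concentration κ ≥ 0 in the doubled
angle (period 180°), a response gain (peak ΔF/F0), and a response sign
(a configurable fraction, default 10%, responds negatively). The von Mises
family was chosen because one parameter spans the full continuum from
untuned (κ = 0 ⇒ flat curve ⇒ OSI 0) to near-single-orientation responders,
so measured OSI can be validated against planted κ.

**Evoked response.** Per trial, the evoked amplitude is

    sign × gain × exp(κ (cos 2(θ − θ₀) − 1)) × exp(−d² / 2)

where d is the lattice distance between the stimulus position and the
cell's receptive field (Gaussian falloff, scale 1 grid step — cells seen
through one lens share almost the same receptive field, and neighbors on the
grid partially drive them). The amplitude multiplies a unit-peak
double-exponential kernel (rise 0.2 s, decay 1.0 s, representative of slow
GCaMP6s-class indicators; both configurable) placed at the frame nearest the
onset, evaluated out to 8 decay constants. I.i.d. Gaussian noise (default sd
0.15 in ΔF/F0 units) is added per frame. Default frame rate is 10 fps, the
top of the 6–10 fps acquisition range, so the 166-ms decoding step spans
about 1.66 frames.

What this emulates: condition-balanced designs, slow indicator kinetics with
realistic trial-to-trial overlap at 4-s ITIs, negative responders, partially
overlapping cell populations across sessions. What it does not: one-photon
background and neuropil contamination, motion, photobleaching, eye-movement
variability, spiking statistics. Passing tests therefore validate the
*analysis* (formulas, calibration, recovery under known truth), not
robustness to extraction artifacts — those are upstream of this pipeline by
design.

**Second sessions.** `derive_second_session` rigidly transforms footprints
(rotation about the FOV center, then translation), jitters centroids
independently (default bench: 0.5 px), drops a random cell fraction, adds
new cells (rejection-sampled away from every existing soma location —
including cells undetected in that session, since a silent soma still
occupies its tissue), drifts surviving preferred orientations by
Gaussian(0, drift sd), and regenerates traces from a fresh trial table. The
true correspondence ledger travels with the bundle for validation.

## Response extraction

Traces are z-scored per ROI against the whole session (constant traces are
excluded with a warning). Alignment assigns frames to a relative-time grid
at the native frame rate — nearest-frame, no interpolation, matching how
6–10 fps data is treated in practice; windows convert ms→frames half-open
[start, end). Trials truncated by the session edge are dropped with a log
entry. Two baselines coexist deliberately: the −500–0 ms mean is subtracted
per ROI × trial when the tensor is built, and the −1000–0 ms window is the
baseline side of the responsiveness test. The window "peak" statistic is the
signed maximum; negative responders are handled by the OSI sign rule rather
than by rectifying peaks.

## Receptive-field test

The Tukey–Kramer (honest significant difference) procedure compares
per-trial 500–1500 ms means across the 15 position groups. The pass rule —
argmax position significantly different from every *non-neighboring*
position — needs a neighborhood definition; 8-connected lattice adjacency
(ring ± 1 and azimuth ± 1) is used as the most conservative natural reading.
The representative ROI (one per hemisphere) is chosen automatically as the
ROI with the most orientations passing the responsiveness test, ties broken
by larger mean response. The p-values come from the studentized-range
distribution with the Kramer unequal-n adjustment, computed directly
(validated against `statsmodels.pairwise_tukeyhsd` to machine precision in
the tests); a "best-only" mode evaluates just the argmax row, which is what
the pass decision needs and is ~7× cheaper — used for 500-repetition null
calibration. The interpolated response surface (spline over the 3 × 5
lattice) is visualization-only and never feeds downstream statistics.

## Orientation tuning

R(θ) is the signed peak of the *trial-averaged* response time course within
500–1500 ms per orientation (averaging before taking the peak; peaks of
single noisy trials would bias R upward). The OSI is the resultant length in
doubled angle after shifting R so min R = 0; the shift makes the statistic
well-defined for z-scored (possibly negative) responses but also makes it
sensitive near flat curves — a flat curve with tiny perturbations can score
high, which is why the all-equal case is assigned OSI 0 by convention and
why responsiveness gates all population summaries. The negative branch
(computed on −R) competes by absolute value and carries a −1 sign label.
Preferred orientation is ½·atan2(Σ R sin 2θ, Σ R cos 2θ), wrapped to
[−90°, 90°); it is NaN (and excluded from analyses) for flat curves. The
responsiveness test is a two-sided two-sample t-test per orientation
(baseline-window per-trial means vs response-window means) at Bonferroni
α/6; the family is the 6 orientations within one ROI, not the ROI
population.

## Decoding

Features are per-ROI means within the window (the minimal reduction
consistent with feeding "time series data" to a trial-level classifier).
The classifier is a linear-kernel SVM with box constraint 1 in one-vs-one
multiclass coding under seeded, stratified 10-fold CV; performance is
1 − classification loss. The observed-vs-shuffled comparison per sliding
window is a two-sample t-test with the observed side being the 10 per-fold
accuracies — the only reading that makes the stated two-sample test
well-posed, since a session yields one observed mean. The shuffled-label
null (100 repetitions by default) sits at 1/6 for six balanced classes; the
calibration tests check every window and ROI count against 3 binomial
standard deviations at the trial count. Time-course significance is
reported at a configurable threshold; the validation suite uses the
stringent 10⁻⁵ display threshold so seed-fixed pre-onset windows are
checked against a bar that single-window null fluctuations essentially
never cross.

## Cell tracking

Alignment maximizes the correlation of summed-footprint projections over a
translation (subpixel, cross-correlation; spectral whitening is disabled
because it is unstable on sparse blob images with cell turnover) and a
±4° × 0.25° rotation grid. A projection correlation below 0.25 raises an
alignment failure: same-FOV session pairs score ≳ 0.5 even with heavy
turnover, unrelated content below ~0.2.

Candidate pairs are gated at 12 px centroid distance (~one footprint
diameter) to bound the pair set. The same-cell mixture has two components
with independent margins per component: lognormal over centroid distance
and beta over (correlation + 1)/2. EM alternates posterior responsibilities
with weighted moment updates (method-of-moments for the beta shapes);
the component with smaller mean log-distance is "same". Any two-component
family that separates the planted clusters would satisfy the validation
properties; this one keeps both margins on their natural supports.
Initialization labels the nearest quartile of pairs as tentatively-same;
convergence is by relative log-likelihood change (10⁻¹⁰, ≤ 500 iterations),
with non-convergence raised as an error and barely-separated components
flagged. Registration is greedy one-to-one by descending P_same above the
0.5 threshold — conflict resolution is not specified by the procedure this
follows, and greedy is order-independent given distinct scores.

Stability statistics: (i) per matched pair, the Pearson correlation of
trial-averaged 0–2000 ms time courses per orientation, averaged over
orientations, against shuffled pairings (10× the pair count; mismatched
index pairs), two-sample t-test; (ii) Pearson r of OSI over pairs
responsive in both sessions; (iii) the 10°-binned histogram of absolute
preferred-orientation differences against a 10,000-repetition permutation
null (counts divided by the repetition count; chance level = pairs/9).
Uniformity is tested with the exact one-sample KS statistic against
Uniform(0°, 90°) — equivalent in the large-reference limit to a two-sample
test against a sample constructed from theoretical values, and exactly
calibrated. The exponential comparison fits A·e^(−x/τ) to the observed bin
proportions and runs a two-sample KS against a deterministic quantile draw
from the fitted curve truncated to [0°, 90°]; fitting and testing on the
same data biases this second test toward non-rejection, which is inherent
to the procedure as described and is flagged here rather than altered.
Fewer than 3 responsive pairs suppresses the tuning-stability block with a
notice.

## Pipeline

`RunConfig` defaults encode the study constants (windows, 500/166 ms
decoding, 10 folds, 100 shuffles, P_same 0.5); every override is recorded
in the run manifest. One seed fans out to per-stage child seeds via
`SeedSequence` spawning, so stages rerun in isolation reproducibly; the
manifest stores SHA-256 checksums of every output, and identical seeds give
bit-identical manifests.

## Numerical choices and degenerate inputs

- All-equal tuning curves: OSI 0, preferred orientation NaN and excluded.
- Zero-variance groups in t-tests: warned, treated as non-significant.
- Distances are clipped at 10⁻³ px and correlations mapped into
  (10⁻⁴, 1 − 10⁻⁴) before the mixture's log-densities.
- Tie-breaks: representative-ROI by larger mean response; registration by
  smaller distance at equal P_same; OSI branch ties go positive.
- Noise-free oracle benches use 9-s deterministic ITIs so trials are exactly
  isolated: at the default 4 ± 1 s ITI the indicator tail of the previous
  trial overlaps the next trial's window (a realistic effect that the
  min-to-zero OSI shift amplifies for untuned cells), which would confound
  exact-recovery checks aimed at the measurement code itself.

## Problem sizes in the validation suite

Validation runs use sizes chosen to make the statistical checks
well-powered while keeping the whole suite desk-scale: 100-cell sessions
for tuning recovery and tracking (20 trials per orientation), 40 planted +
500 permuted receptive-field fits, 30-ROI decoding benches with 20–30
shuffle repetitions per window, 1000-repetition KS calibration, and
reduced-repetition pipeline runs for the determinism check. The statistics
they compute are calibration and recovery properties of this pipeline under
the generator's assumptions; headline percentages from any particular
recorded dataset are functions of that data and are not reproduced here.

## Known limitations

- The mixture model assumes margin independence within components; strongly
  correlated distance/shape errors (e.g. non-rigid tissue deformation) are
  not modeled, and only two-session rigid registration is supported.
- The min-to-zero OSI shift makes OSI of weakly responsive ROIs noisy;
  gate on responsiveness before interpreting population OSI distributions.
- The exponential KS test inherits the fitted-null bias described above.
- Nearest-frame alignment leaves up to half a frame (≤ 50 ms at 10 fps) of
  onset quantization; at 6–10 fps this is well below the response
  timescale.
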