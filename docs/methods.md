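# Methods

This note documents the models and numerical choices behind `oxtmod`: the
forward model the synthetic generator implements, the analysis procedures,
the parameters that matter, and what the synthetic benchmarks do and do
not establish about real recordings.

## The analysis model

### ΔF/F and windows

ΔF/F = (F − F₀)/F₀ with F₀ the per-neuron mean fluorescence over every
frame strictly before the first scheduled event. The baseline window
length is therefore set by the schedule (the presets leave 60 s before the
first cue); it is overridable by editing the schedule, not by a separate
parameter, so the baseline definition can never disagree with the events
used for alignment.

Window summaries use the **mean** (not the sum) of ΔF/F over the window,
so values stay in ΔF/F units and the 0.05 classification threshold has the
same meaning for the 60-s, 30-s, and 5-s windows. Event-to-frame alignment
is causal: a window anchored at time *a* begins at the first frame with
timestamp ≥ *a*. Frames are 237–711 ms, so sub-frame onsets are
unavoidable; the causal convention never attributes pre-onset frames to a
response. A consequence worth knowing: two event types whose onsets sit at
different sub-frame phases integrate slightly different grids, so
"identical" responses differ at the ~10⁻⁶ ΔF/F level — far below the 0.05
threshold, but visible to exact-equality tests.

### Smoothing

The 3-frame zero-phase filter is a causal 3-point moving average applied
forward and then backward (net impulse response (1,2,3,2,1)/9), with
reflect padding so trace ends are not biased toward zero. Smoothing is
applied before correlation only; classification integrates unsmoothed
ΔF/F (a window mean is already an aggregate).

### Dye-drift subtraction

Nose-exposed fish absorb the TRPA1 photoswitch over the session, adding a
slow ramp to every ROI. A least-squares line is fitted to a non-indicator
background ROI and its time-varying component, slope × (t − t₀), is
subtracted from every neuron before ΔF/F. The intercept is deliberately
not subtracted: each neuron keeps its own baseline level and raw values
stay positive.

### Regressors and correlation

The indicator kernel is a delayed single exponential — zero before the
0.48-s response delay, exp(−(t − delay)/3 s) after, unit peak. No rise
time is modelled; at 474-ms frames a sub-frame rise is unidentifiable, and
the kernel is swappable (`KernelParams`) if a different indicator is used.
Stimulus regressors are event boxcars convolved with this kernel and
renormalised to unit peak; events shorter than the internal grid step
(the 100-ms UV pulse) are rendered as impulses. Motor regressors are
impulse trains at bout onsets, split stimulus-associated vs spontaneous at
5 s post-UV and small vs large at 50°; bouts are **not** weighted by
amplitude (a documented choice — the size split already carries the
amplitude information the class rules use).

"Correlation" is zero-lag Pearson: the kernel's delay parameter already
encodes the haemodynamic-style lag, making a lag search redundant.
Constant traces and empty-category regressors yield r = 0 with a
degeneracy flag rather than NaN.

### Classification

call = enhanced if Δ > θ, suppressed if Δ < −θ, else no-change, where Δ is
the cue-minus-control difference of per-neuron window means averaged over
repeats and θ = 0.05 ΔF/F. The boundary is strict ("more than"), so
|Δ| = θ is no-change. For UV-anchored windows the cue/control split is by
trial: a UV event belongs to the most recent preceding cue. The same θ is
used for all windows (configurable); because windows are means, this is
self-consistent. θ is arbitrary in origin, which is why `threshold_sweep`
exists: on all presets the suppressed/enhanced ordering is stable across
θ ∈ [0.01, 0.15].

### Clustering and class rules

k-means (scikit-learn; k-means++ seeding, best of 50 restarts, seeded) on
the neuron × regressor correlation matrix with k = 12 for headline runs.
`select_k` reports BIC/AIC over a spherical-Gaussian hard-assignment
likelihood (X-means form, pooled variance σ² = inertia/(d(n−k)), including
the cluster-proportion term n_j log(n_j/n); p = k·d + 1). The proportion
term matters: without it, splitting a single Gaussian always improves the
criterion. BIC/AIC is a diagnostic only — k stays fixed at 12 across
datasets for comparability.

Grouping clusters into broad classes is usually done by eye; here it is an
explicit, editable rule table over centroid correlations: stimulus bands
high ≥ 0.5, moderate 0.2–0.5, weak 0.05–0.2, anticorrelated ≤ −0.2, and a
motor axis (max over spontaneous-bout regressors) ≥ 0.2. Rules are ordered
and exhaustive (anticorrelated → stimulus+motor → motor-only → stimulus
bands → unresponsive); a centroid matching no rule is an error, not a
silent drop.

### pERK

Intensities are normalised to the mean of control cells (PO and PT pooled,
or per region). The active-cell threshold is the empirical 90th percentile
(linear-interpolation quantile) of control normalised values; a cell is
active iff strictly above it, making the control active count
⌊0.10·n⌋ by construction (±1 under ties). The PO/PT split is an
anterior–posterior cutoff carried in the table, supplied by the user, not
inferred. Whether "active" should be defined on raw or normalised values
is ambiguous in principle; normalised is used because the 10% rule is
stated on normalised values and it makes the threshold scale-free.

### Behavior

Bouts are peaks of |cumulative angle| found with prominence 10°, minimum
separation 100 ms, on a 5-sample moving average of the 200-fps trace
(≈1% amplitude loss on a 200-ms bout, but it keeps frame noise well below
the prominence criterion); kinematics are measured on the raw trace. The
bout onset is the last pre-peak entry into a ±5° rest band. Large means
peak |angle| strictly above 50°. Epoch assignment precedence when windows
overlap is post-TRPA1 > post-cue > precue (most specific wins), with a
warning. These detector parameters are package defaults, all configurable;
no canonical values exist for them.

### Statistics

Signed-rank for paired, rank-sum for independent samples, Kruskal–Wallis
with Tukey–Kramer correction for multi-group (studentized-range criterion
on mean ranks with tie correction — the classical multiple-comparison
procedure on rank sums). All delegated to scipy; the pipeline's own
exactness guarantees concern its computations, not re-derived test
distributions. All-tied paired differences return p = 1 with a degeneracy
flag.

## The forward model (synthetic generator)

The generator exists to make every stage falsifiable: it renders the data
the analyses assume, plants the answers, and hides them from the analysis
path.

**Schedules.** Cues alternate control water with one test cue at a fixed
ISI (5 min for OXT-style runs), 10-s pulses, first onset at 60 s so a
baseline exists; optionally each cue is followed 30 s later by a 100-ms
UV/TRPA1 pulse.

**Traces.** Raw F = baseline_F · (1 + signal + ε) + drift·t, with ε i.i.d.
Gaussian per frame (ΔF/F units) and signal the sum of unit-peak kernel
responses: a mild water-flow response to every cue pulse (0.05 ΔF/F,
identical on cue and control trials so it cancels in Δ), the
tuning-class response, and the planted modulation. Noise is white beyond
the kernel — the simplest model consistent with using a 3-frame smoother;
real recordings have temporally structured noise the generator does not
emulate. Noise SD is a free parameter (nothing calibrates it to real
data); the presets use 0.025 ΔF/F = effect/8.

**Mixtures are planted as exact counts** (largest-remainder rounding,
randomly permuted across neurons), not i.i.d. draws: recovery benchmarks
then measure classification error rather than the Monte Carlo error of the
label draw, while the expected composition is identical. At 1000 neurons
an i.i.d. draw alone would scatter recovered fractions by ±3 percentage
points, swamping the quantity of interest.

**Tuning classes** scale stimulus (UV impulse) and motor (spontaneous-
bout impulse) responses. The gains (strong 1.0, moderate 0.35, weak 0.19,
anticorrelated −0.35, motor 0.6, mixed 0.6/0.5, × effect size) are
calibrated so each class's correlation with its regressor lands near the
middle of its class-rule band under the preset noise — the classes are
*defined* by those bands, so the forward model must realise them; a weak
class planted at the band floor is not a weak-band class but a coin flip.

**Modulation** (what the test cue does to a neuron in a given window) is
planted additively on test-cue trials as a sustained response spanning the
analysis window — a 60-s boxcar for cue windows, a 20-s boxcar for the
pre-TRPA1 window (it relaxes, τ = 3 s, before the UV pulse so windows stay
independent), and an impulse at the UV time for the post-TRPA1 window —
convolved with the same kernel, amplitude ±effect. A response confined to
the 10-s cue pulse would average to ~0.17 × effect over a 60-s window and
fall below the 0.05 threshold at any plausible effect size; tonic
suppression/enhancement across the window is also the phenomenon the
modulation models. Planted window-mean deltas are therefore ~0.95·effect
(60-s), ~0.66·effect (30-s) and ~0.47·effect (5-s) — all ≥ 2.8× threshold
at effect 0.2.

**Tail traces** are half-sine angle envelopes (default 200 ms) at 200 fps:
spontaneous bouts at a Poisson rate (kept out of the 5-s post-UV windows
so the truth split is exact), optional stimulus-locked bouts within 5 s of
each UV event, amplitudes straddling 50° (small ~N(30°, 8°) clipped to
≤50°, large ~N(70°, 10°) clipped to >50°), plus white angle noise.

**pERK tables** are lognormal intensities whose group location is the
control location times a planted multiplier; PO/PT membership and AP
positions are drawn uniformly within region ranges.

**Seeding.** Every stochastic operation derives from one master seed via
`numpy.random.SeedSequence` spawns in a fixed order (classes, modulation,
noise; per-fish tail seeds from a fixed offset), so a run is byte-
reproducible from its manifest.

### Presets

`fig2-kin` / `fig2-nonkin` / `fig2-adult` plant the suppressed/enhanced
mixtures observed for kin (27.5%/10%), non-kin (18%/23%) and adult
(14%/46%) conditioned-water cues in the 60-s window; `fig6-trpa1` plants
54%/32% (post-TRPA1) and 43%/30% (post-cue) kin-water modulation on top of
a tuning mixture mirroring the observed broad-class proportions
(3.2/25.2/8/31.2/12.8/12.8/6.8% for strong/moderate/weak TRPA1, mixed,
motor, unresponsive, anticorrelated). Effect size 0.2 ΔF/F (4× threshold),
noise 0.025. Preset sizes are desk-scale study conditions: 200–500 neurons
default, rescalable (the recovery analyses use 1000).

## What the benchmarks show — and don't

Passing recovery tests shows the pipeline is a correct inverse of this
forward model at these SNRs: calls match planted labels with accuracy 1.0
at effect/noise = 8, recovered fractions match planted mixtures to
multinomial sampling error, bout detection F1 ≥ 0.98 at amplitude/noise
≥ 5. It does **not** show the 0.05 threshold or band edges are optimal for
real recordings, whose noise is autocorrelated, whose responses adapt
across repeats, and whose modulation is not a clean sustained offset.

Known limitations, deliberate:

- **Band-based class rules require unmodulated tuning structure.** The
  additive modulation contributes variance orthogonal to every regressor,
  depressing correlations heterogeneously across neurons; class-recovery
  benchmarks therefore run with modulation disabled. On modulated runs the
  cluster *structure* is still recovered, but fixed band edges misband
  borderline classes — the same caveat applies to by-eye grouping of real
  data.
- No spike-train biophysics, no pixel-level movies, no swim
  hydrodynamics, no neuropil contamination, no motion artefacts: the
  generator starts where the pipeline starts, at extracted traces.
- Two-sided ties in rank tests follow scipy's conventions; degenerate
  inputs are flagged, not guessed.

## Parameter reference

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| kernel delay | 0.48 | s | indicator response delay |
| kernel τ | 3.0 | s | indicator decay time constant |
| threshold θ | 0.05 | ΔF/F | response-call boundary (strict) |
| windows | 60 / 5 / 30 / 10+30 | s | post-cue / post-TRPA1 / pre-TRPA1 / optogenetic split |
| k | 12 | – | clusters for headline runs |
| n_init | 50 | – | k-means restarts |
| subsampling | 25 / 200 | neurons | per fish / per group |
| active-cell α | 0.10 | – | control fraction above threshold |
| angle cut | 50 | deg | large vs small bouts (strict >) |
| motor stim window | 5 | s | bout counts as stimulus-associated |
| bout prominence / separation / rest band | 10 / 0.1 / 5 | deg, s, deg | detector defaults |
| frame interval | 0.474 | s | two z-planes at ~237 ms |
| effect size | 0.2 | ΔF/F | planted modulation amplitude |
| noise | 0.025 | ΔF/F | per-frame Gaussian SD |
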