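# Methods

This note documents the models, estimators and numerical choices behind
`micardia`, in the spirit of a methods appendix: what each stage computes,
which parameters matter, what the synthetic data do and do not emulate, and
where genuinely open design decisions were resolved.

## The experimental model

The package targets cue-paced go/nogo foot motor imagery: a subject watches
a screen; every 11–14 s (uniform) a 2 s cue appears, green (*go*: imagine a
brisk dorsiflexion of both feet) or red (*nogo*: withhold it), with 50 %
probability; three runs of 40 trials are recorded.  Signals: 15 EEG channels
arranged as three 5-electrode crosses over C3, Cz and C4 (centre + 4
orthogonal neighbours at 2.5 cm), 2 integrated-EMG channels from the
tibialis anterior of each leg, and 1 bipolar ECG channel — all at 250 Hz.

Two coupled responses are quantified:

* **ERD/ERS** — the percentage decrease (event-related desynchronisation)
  or increase (synchronisation, "beta rebound") of beta-band EEG power
  relative to a pre-cue reference.  Both conditions show an early, automatic
  ERD dip near 400 ms; imagery deepens it and adds a peri-imagery ERD and a
  delayed rebound; withholding is followed by a rebound peaking near 1 s.
* **Cue-locked heart-rate change** — a brisk deceleration bottoming out near
  650 ms (larger under nogo), followed in the go condition by an
  acceleration attributed to mental effort.  The go-minus-nogo difference
  ("hypothetical" HR response) isolates that acceleration.

## Estimators

### Inter-trial variance ERD/ERS (`erd.erd_timecourse`)

Per frequency band: 5th-order Butterworth band-pass, applied zero-phase
(forward–backward; the effective order doubles, accepted because zero-phase
filtering preserves peak latencies, which are reported features) → subtract
the per-sample ensemble average across trials, which removes phase-locked
evoked components so only induced power remains → square → average across
trials → 250 ms centred moving average (edge samples use the partial
window) → percent change `100·(P(t) − P̄_ref)/P̄_ref`, with `P̄_ref` the mean
smoothed power over the reference interval.  The default reference is 2–4 s
before the cue; 1–0 s ("pre10"/"pre01" — the same interval, named in both
printed orders) is available for the alternative-reference analyses.
Windows are half-open `[a, b)` in samples; time 0 is the cue-onset sample.

Smoothing is applied to the *power*, before the percent transform, so the
ratio's denominator is not distorted.  Note that a zero-phase filter's
boundary handling collapses across-trial variance at the outermost epoch
samples; with a [−5, +6] s epoch all analysis windows sit well inside the
affected margin (~1 s for the narrowest 2 Hz bins).

### Box-Cox significance (`erd.boxcox_significance`)

Band-power samples are strongly right-skewed, so the per-sample significance
interval is built after a Box-Cox transform: λ is estimated by profile
maximum likelihood on the pooled reference-window power and applied
everywhere.  The null interval for a single time sample's cross-trial mean
is `μ̂ ± t_{1−α/2, n−1}·s/√n`, where `s²` is the across-trial variance at
individual reference samples pooled over the reference window.  The variance
is estimated per sample (not from per-trial window means) because a window
mean averages over many samples and would badly understate the variance a
single sample's mean actually has — per-sample pooling calibrates the
false-positive rate to ≈ α, which the test suite checks by Monte-Carlo.
An all-constant reference yields a zero-width interval (λ set to 1, tiny
floating-point guard band), so any deviating sample is flagged.

### Time–frequency maps and band selection

Maps apply the single-band estimator over contiguous 2 Hz bins from 8 to
44–45 Hz (18 bins; the last full bin below 45 Hz) with the Box-Cox mask at
α = 0.05; only significant cells are rendered (ERD red, ERS blue).

Subject-specific reactive bands are chosen on motor-*execution* go trials,
where the post-movement beta rebound is much stronger than after imagery:
for every candidate band (all contiguous unions of 1–4 adjacent 2 Hz bins),
per-trial log band power in the rebound window (default 0.5–2.5 s — a
choice; no canonical numeric window exists) and in the reference window are
classified by a leave-one-out midpoint-threshold rule, and Cohen's kappa of
the resulting confusion matrix scores the band.  Ties prefer the wider
band, then the lower low edge.  The midpoint-threshold classifier is itself
a design choice; the kappa criterion is standard in this literature, but
the classifier behind it is not canonically fixed.

### Cardiac chain (`cardiac`)

QRS detection follows the filter-bank family: four sub-bands spanning
5–40 Hz, summed squared sub-band signals smoothed over 80 ms, adaptive
two-level (signal/noise) thresholding with a 250 ms refractory period and a
back-search at half threshold when a gap exceeds 1.66× the running R-R
mean, then refinement of each beat to the raw-signal extremum within
±40 ms.  Refractory period and sub-band layout are standard values for this
detector family.

The instantaneous HR assigns `60/RRI_k` bpm to each R-R interval and
interpolates linearly, sampled on the 250 Hz session clock, constant beyond
the first/last anchor.  The anchor convention is *midpoint* of the interval
by default: `60/RRI` is the interval-average rate, so midpoint anchoring is
time-unbiased for event-locked averaging, whereas end-anchoring (available
via `anchor="end"`) delays the apparent response by about half an R-R
interval (≈ 0.35 s at rest) — enough to corrupt the headline dip latency.
Intervals outside 0.3–2.0 s are flagged suspect but retained; trial-level
rejection is the sanctioned removal path.

Cue-locked responses are computed per trial as percent change against that
trial's own pre-cue reference mean, then averaged.  Per-trial referencing
removes the slow background fluctuations (~0.1 Hz and ~0.25 Hz, several
percent of mean HR) that would otherwise swamp the ~2 % event-locked
deceleration.  The hypothetical response is the pointwise go−nogo
difference; it is exactly linear in its inputs.

### Trial rejection (`rejection`)

*EMG rule*: per trial and leg, rest mean μ and SD σ over the trial's own
5 s pre-cue window; reject if any post-cue sample exceeds μ + kσ, with k = 3
for nogo and k = 5 for go (imagery can raise the tonus of the target
muscles).  A zero-variance rest window degrades the threshold to μ with a
warning.  *HR rule*: per condition, pool the per-sample |ΔHR| of all
surviving trials over the full epoch, compute Q1/Q3/IQD (quartiles by
linear interpolation between order statistics, the common "type 7" rule —
a convention that must be pinned down explicitly, recorded in the report for
auditability), remove every trial containing a value outside
`[Q1 − 1.5·IQD, Q3 + 1.5·IQD]`, repeat to a fixed point.  Whole-trial
removal makes the procedure order-free, idempotent and terminating in at
most n iterations.  EMG-removed trials are never re-examined by the IQR
rule.

A property worth knowing: because the IQR rule targets trials with extreme
HR *derivatives*, it mildly prefers to remove trials whose apparent
cue-locked change is extreme, which shades the surviving grand-average dip
a tenth or two of a percentage point shallower.  That is the
procedure behaving as designed, not an implementation artifact; the
verification harness quantifies it.

### Group statistics (`stats`)

Significance bands use the t-percentile bootstrap: resample subjects with
replacement (500 resamples by default), collect the studentised statistic
`t* = (mean* − mean)/se*` per time sample, and form the band from its
empirical α/2 and 1−α/2 quantiles; a sample is significant when zero falls
outside the band.  The resampling unit is the subject; a trial-level option
exists for single-subject use.  No correction across time samples is
applied — this mirrors the per-sample display convention customary for such
group curves and is a reproduction choice, not a statistical endorsement.
Zero-variance samples give a degenerate band equal to the mean (significant
exactly when that mean is nonzero).  Condition comparisons bootstrap the
per-subject paired differences and report the earliest post-cue significant
sample.  Feature-level tests are the classical two-sided paired t
(df = n−1) and Pearson product-moment correlation (p from the t transform,
df = n−2).

## The synthetic-session generator

The generator exists so every stage can be verified by parameter recovery;
its defaults *are* the study conditions (paradigm timing above; planted
effect sizes are the reported group means: ERD −39.82 %/−32.00 % at
471/397 ms for go/nogo, HR −1.00 %/−1.94 % at 640/652 ms, background HR
rhythms at 0.1 and 0.25 Hz).

**EEG.**  Each channel is 1/f (pink) noise — 3 µV RMS shared within each
Laplacian group plus 1 µV independent per channel — carrying a beta
oscillation (carrier at the centre of the subject's band, default
20–28 Hz): 10 µV on the foot-area (Cz) centre, half that on its neighbours
(coherent), 5 µV unmodulated on the hand-area groups.  Because the shared
noise and half the oscillation are common mode, the Laplacian derivation
raises the modulation SNR, which a test asserts.  The planted percent
band-power profile g(t) enters as the amplitude envelope `√(1 + g/100)`, so
the in-dip power ratio equals 1 + depth/100 by construction.  The profile
model: both conditions share one automatic early dip (Gaussian, σ = 0.26 s,
planted with the nogo depth/latency — the orienting component); the go
condition adds an imagery-preparation component whose amplitude and centre
are solved numerically so the go curve's early minimum sits exactly on the
planted go depth/latency, plus a peri-imagery ERD plateau (−25 % over
0.9–2.5 s) and a post-imagery rebound (+30 % near 3.5 s); the nogo
condition instead rebounds (+30 %) at 1 s.  All profiles are gated to begin
≈100 ms after the cue (visuomotor delay), so the conditions diverge from
roughly 200 ms — matching the qualitative onset of the reported
condition difference.

**ECG.**  Beats come from integral-pulse frequency modulation of the
planted instantaneous rate
`r(t) = 88 bpm · (1 + slow fluctuations + cue-locked response)`; each beat
is rendered as a Ricker (Mexican-hat) wavelet, σ = 20 ms (≈80 ms visible
width), 1 mV.  Slow fluctuations are two sinusoids (0.1 and 0.25 Hz,
1.5 % each, random phases).  The deceleration is a sharp causal core
(asymmetric Gaussian, 0.33/0.45 s, 20 % of depth) on a broad symmetric
pedestal (σ = 1.3 s, 80 % of depth, gated to develop only in the last
~1.5 s before the cue).  This split is deliberate: assigning `60/RRI` to an
interval and interpolating is equivalent to smoothing the rate signal with
a boxcar∗triangle kernel of R-R width, under which a single Gaussian dip
either loses ~20 % of its depth (if curved) or its latency anchoring (if
flat-bottomed); the core fixes the latency, the pedestal carries the depth.
The go acceleration (+1.5 % at 2 s, asymmetric 0.4/0.8 s) has a slow enough
onset not to tilt the dip minimum.  An optional white beat-timing jitter
(`rr_jitter_ms`) exists but defaults to 0: real short-term HR variability
is dominated by smooth respiratory modulation, and white beat-scale jitter
turns the per-trial maximum |ΔHR| into an extreme-value statistic that
makes the iterative IQR rule reject a third of clean trials.

**EMG.**  The integrated-EMG baseline is bounded positive noise (mean of
two uniforms, ≈2.45 SD maximum deviation), so clean trials can never trip
the 3σ rule — by design, the generator's false-alarm rate is zero, which
real EMG does not guarantee.  Planted artifact trials receive a half-sine
burst on the left leg whose peak equals exactly `rest mean + 6·SD` of that
trial's own pre-cue window, guaranteed above both thresholds.

**Cohorts.**  Per-subject effects are Gaussian perturbations of the
population values, truncated to valid ranges: ERD depth SD 4 pp, ERD
latency SD 30 ms, HR depth SD 0.15 pp, HR latency SD 50 ms, band shift SD
0.5 bins (all scaled by `subject_sd_scale`).  These spreads are
deliberately smaller than realistic between-subject spreads (which run
~20 pp for ERD depth): with realistic spreads, the grand-average sampling error
alone (SD/√16 ≈ 5 pp) would dominate recovery measurements, and the
generator's purpose is to probe estimator fidelity, not cohort sampling
noise.  Consequently, recovery tests passing here says the *pipeline* is
faithful; it says nothing about single-study power under real
between-subject variability.

**What the generator does not emulate:** eye blinks and EOG, non-stationary
background spectra, realistic ECG morphology (P/T waves), respiration
beyond a sinusoidal HR component, electrode drift, or line noise.

## Verification harness and expected biases

`micardia.verify` regenerates preset cohorts and pushes them through the
same stages as the pipeline.  Under the default conditions the known,
quantified biases are: ERD depth readings shallower by ~1–2 pp (250 ms
smoothing of a σ = 0.26 s dip retains ≈96 %, in-band noise floor ≈99 %,
subject latency jitter ≈99 %); HR dip readings shallower by ~0.2–0.3 pp
(R-R sampling kernel ≈89 % retention, IQR trial selection ~0.1–0.2 pp) and
later by ~50–80 ms.  Grand-average minima on 16-subject cohorts land within
±5 pp / ±60 ms (ERD) and ±0.5 pp / ±150 ms (HR) of the planted values in
≥ 90 % of seeded runs; the acceptance suite asserts exactly that.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator` seeded from
  `SeedSequence` trees; identical seeds give bit-identical sessions and
  byte-identical serialized pipeline outputs.
* Tie-breaks: curve minima return the first (earliest) occurrence; band
  selection prefers wider, then lower-edge bands.
* Epoch window [−5, +6] s: contains the 2–4 s reference, the 1–0 s
  alternative reference, the rebound (~1 s) and the HR acceleration (~2 s)
  with smoothing margins; trials that would cross a recording edge are
  dropped and counted.
* Degenerate inputs raise typed errors (`micardia.errors`) rather than
  propagating NaNs: flat ECG, < 2 trials, empty epoch selections,
  zero-variance correlations, all-trials-rejected.
* Problem sizes in the test suite (cohort sizes, resample counts, record
  lengths) follow the preset study conditions where a criterion depends on
  them (16 subjects, 3×40 trials, 500 resamples for inference; 200
  resamples and reduced cohort counts for Monte-Carlo calibration), and are
  scaled down only where the quantity under test is size-independent.

## Known limitations

* EDF support writes a minimal but standard-conformant 16-bit EDF; events
  travel in a plain-text sidecar, not EDF+ annotations.
* The Box-Cox interval construction and the kappa classifier are this
  package's own concrete realisations of loosely specified conventions; results depending
  delicately on either should be interpreted accordingly.
* Per-sample significance displays carry no multiplicity control.
* The Pearson feature correlations at n = 16 are reported for layout
  fidelity; they are underpowered at this sample size.
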