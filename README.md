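# micardia

Coupled EEG/heart-rate analysis of cue-paced **go/nogo foot motor imagery**,
with a synthetic-session generator that makes every stage verifiable by
parameter recovery.

When a visual cue tells a subject to execute or withhold kinesthetic motor
imagery, two things happen within the first second: the sensorimotor beta
rhythm over the foot area desynchronises (an early **ERD** dip, maximal near
400 ms), and the heart briskly decelerates (minimum near 650 ms).  Both are
automatic orienting-type responses; executing the imagery deepens the ERD
and adds a heart-rate acceleration attributed to mental effort.  This
package implements the full analysis chain for such experiments:

* **ERD/ERS quantification** by the inter-trial variance method: zero-phase
  5th-order Butterworth band-pass, ensemble-average subtraction (removes
  phase-locked evoked activity), squaring, trial averaging, 250 ms
  smoothing, and percent change against a 2–4 s pre-cue reference —
  `ERD(t) = 100·(P(t) − P̄_ref)/P̄_ref`, ERD < 0, ERS > 0.  Per-sample
  significance via a Box-Cox transform; time–frequency maps over 2 Hz bins
  (8–45 Hz); subject-specific band selection by Cohen's-kappa
  discriminability of the motor-execution beta rebound.
* **Cardiac chain**: filter-bank QRS detection with adaptive two-level
  thresholding, R-R intervals, instantaneous HR (60/RRI, linearly
  interpolated), per-trial percent-referenced cue-locked responses, and the
  go-minus-nogo "hypothetical" response that isolates the effort-related
  acceleration.
* **Trial rejection** with provenance: integrated-EMG thresholds at rest
  mean + 3·SD (nogo) / + 5·SD (go), and iterative class-wise 1.5×IQR
  rejection on the absolute first derivative of the HR.
* **Group statistics**: t-percentile bootstrap significance bands
  (subject-level resampling, 500 resamples, α = 0.05/0.01), per-sample
  condition comparisons, paired t-tests and Pearson correlations on
  extracted features, and a latency/amplitude feature table.
* **Synthetic sessions**: 15-channel EEG (pink noise + amplitude-modulated
  beta over three Laplacian groups), IPFM-generated ECG with planted
  cue-locked rate responses, and integrated-EMG with planted artifact
  bursts — 3 runs × 40 trials, 50 % go, 11–14 s inter-cue interval, 250 Hz,
  with analytic ground truth for every planted effect.

See [`docs/methods.md`](docs/methods.md) for the models, assumptions and
numerical choices, and [`examples/`](examples/) for one short script per
capability.

## Worked example

```python
import micardia as mc

session, truth = mc.generate_session(seed=7)          # one synthetic subject
lap = mc.laplacian(session, "Cz")                     # foot-area derivation

epochs = mc.epoch(lap, session.events, 250.0, (-5, 6), condition="go")
curve = mc.erd_timecourse(epochs, band=truth.beta_band_hz)
print(mc.extract_minimum(curve))

beats = mc.detect_qrs(session.ecg, 250.0)
hr = mc.hr_signal(beats, session.n_samples, 250.0)
print(mc.extract_hr_minimum(mc.hr_response(hr, session.events, "go")))
```

Running `python examples/02_erd_curve.py` prints:

```
go   : early ERD minimum -38.63 % at 468 ms (50 trials, 1009 significant samples)
nogo : early ERD minimum -31.24 % at 368 ms (70 trials, 383 significant samples)
```

i.e. the estimator reads back the planted effect structure (−39.82 % at
471 ms go, −32.00 % at 397 ms nogo) to within single-subject estimation
noise and smoothing attenuation.  `examples/03_heart_rate_response.py` does
the same for the cardiac chain:

```
go   : HR minimum -0.75 % at 624 ms (62 trials)
nogo : HR minimum -1.99 % at 660 ms (58 trials)
hypothetical (go-nogo) peak: +1.75 % at 1.96 s
```

## Command line

A thin CLI wraps the library for batch use:

```bash
mi-cardia simulate -n 16 -s 1 -o sessions/        # synthetic cohort to disk
mi-cardia run -n 16 -s 1 -o out/                  # full pipeline + figures
mi-cardia report -b out/                          # re-render from provenance
```

`run` produces grand-average ERD and HR curves with bootstrap bands (TSV),
a feature table, rejection reports with per-trial rule provenance, figures
(time–frequency maps, HR-over-ERD grand averages, the first-second ERD
comparison, the HR difference panel, the ERD-vs-HR scatter) and a markdown
report; every output embeds the config hash and seeds, and identical seeds
reproduce outputs byte for byte.

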