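"""Generate one synthetic go/nogo motor-imagery session and look inside.

The session mimics the recorded paradigm: 3 runs x 40 trials, 50 % go cues,
inter-cue interval uniform on 11-14 s, 15 EEG + 2 EMG + 1 ECG channels at
250 Hz.  The ground truth records what was planted, so any analysis result
can be compared against it.
"""

import numpy as np

import micardia as mc

session, truth = mc.generate_session(seed=1, artifact_fraction=0.1)

print(f"duration            : {session.duration_s:.1f} s "
      f"({session.n_samples} samples at {session.sample_rate_hz:.0f} Hz)")
counts = session.events["label"].value_counts()
print(f"cue events          : {len(session.events)} "
      f"({counts.get('go', 0)} go / {counts.get('nogo', 0)} nogo)")
gaps = np.diff(session.events["onset_sample"]) / session.sample_rate_hz
print(f"inter-cue interval  : {gaps.min():.1f} - {gaps.max():.1f} s")
print(f"planted EMG bursts  : {truth.artifact_flags.sum()} trials")
print(f"subject beta band   : {truth.beta_band_hz[0]:.0f}-{truth.beta_band_hz[1]:.0f} Hz")
print(f"true heart beats    : {len(truth.beat_times)} "
      f"(mean rate {60 * len(truth.beat_times) / session.duration_s:.1f} bpm)")

# planted response summary: the percent curves every stage should recover
for cond in ("go", "nogo"):
    t, g = truth.epoch_times, truth.erd_truth[cond]
    m = (t > 0) & (t <= 1)
    print(f"planted ERD minimum ({cond:5s}): {g[m].min():6.2f} % "
          f"at {1000 * t[m][np.argmin(g[m])]:.0f} ms")
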