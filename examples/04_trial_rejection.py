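"""Both trial-rejection rules with full provenance.

EMG rule: a trial goes if any post-cue sample of either leg's integrated EMG
exceeds rest mean + k * SD over that trial's own 5 s pre-cue window (k=3 for
nogo, k=5 for go — imagery may raise muscle tonus).  HR rule: iterative
class-wise IQR rejection on the absolute first derivative of the
interpolated heart rate.
"""

import micardia as mc

session, truth = mc.generate_session(seed=3, artifact_fraction=0.2)
fs = session.sample_rate_hz

beats = mc.detect_qrs(session.ecg, fs)
hr = mc.hr_signal(beats, session.n_samples, fs)

for cond in ("go", "nogo"):
    left = mc.epoch(session.emg[0], session.events, fs, (-5, 6), cond)
    right = mc.epoch(session.emg[1], session.events, fs, (-5, 6), cond)
    keep_emg, report = mc.emg_reject(left, right, cond)

    planted = truth.artifact_flags[truth.labels == cond]
    print(f"{cond:5s}: EMG rejected {int((~keep_emg).sum()):2d}/{len(keep_emg)} "
          f"trials (planted bursts: {int(planted.sum())}, "
          f"all caught: {bool((~keep_emg[planted]).all())})")

    hr_ep = mc.hr_epochs(hr, session.events, cond).subset(keep_emg)
    keep_iqr, rep_iqr = mc.hr_iqr_reject(hr_ep, cond)
    iters = rep_iqr.table["iteration"].dropna()
    print(f"       IQR rejected {int((~keep_iqr).sum()):2d}/{len(keep_iqr)} "
          f"survivors in {int(iters.max()) if len(iters) else 0} iteration(s) "
          f"[quartiles: {rep_iqr.quartile_rule}]")
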