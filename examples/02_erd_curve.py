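"""Quantify the beta-band ERD/ERS of one subject and compare with the truth.

Chain: small-Laplacian derivation over the foot area (Cz) -> cue-locked
epochs -> inter-trial variance estimator (band-pass, ensemble-average
subtraction, squaring, averaging, 250 ms smoothing) -> percent change
against the 2-4 s pre-cue reference.  Negative values are ERD (cortical
activation), positive values ERS (the beta rebound).
"""

import micardia as mc

session, truth = mc.generate_session(seed=7, artifact_fraction=0.0)
lap = mc.laplacian(session, "Cz")

for cond in ("go", "nogo"):
    epochs = mc.epoch(lap, session.events, session.sample_rate_hz,
                      window=(-5, 6), condition=cond)
    curve = mc.erd_timecourse(epochs, band=truth.beta_band_hz)
    lat, amp = mc.extract_minimum(curve)
    n_sig = int(curve.significant.sum())
    print(f"{cond:5s}: early ERD minimum {amp:6.2f} % at {1000 * lat:.0f} ms "
          f"({epochs.n_trials} trials, {n_sig} significant samples)")

print()
print("planted values     : go -39.82 % @ 471 ms, nogo -32.00 % @ 397 ms")
print("the recovered minima should sit within a few percentage points and a")
print("few tens of ms of the planted values; the residual gap is smoothing")
print("attenuation plus single-subject estimation noise")
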