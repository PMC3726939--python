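"""Parameter-recovery harnesses: run the analysis chain on generated cohorts
and measure how well the planted effects are recovered.

These functions exist because the synthetic-data module's purpose is to make
every analysis stage verifiable: they generate a cohort with the preset
effect structure, push it through the same stages the full pipeline uses
(Laplacian → EMG rejection → epoching → ERD; QRS → HR → IQR rejection →
response), and report grand-average features next to the planted truth.
"""

from __future__ import annotations

import numpy as np

from . import cardiac, erd, rejection, stats, synthetic
from .montage import FOOT_DERIVATION
from .session import DEFAULT_WINDOW, GO, NOGO, epoch, laplacian

CONDITIONS = (GO, NOGO)


def _emg_keep(session, cond, window):
    left = epoch(session.emg[0], session.events, session.sample_rate_hz, window, cond)
    right = epoch(session.emg[1], session.events, session.sample_rate_hz, window, cond)
    keep, _ = rejection.emg_reject(left, right, cond)
    return keep


def recover_erd(
    seed: int,
    n_subjects: int = 16,
    paradigm: synthetic.ParadigmSpec | None = None,
    effects: synthetic.EffectSpec | None = None,
    artifact_fraction: float = 0.1,
    window: tuple[float, float] = DEFAULT_WINDOW,
    reference_window: tuple[float, float] = (-4.0, -2.0),
) -> dict:
    """Grand-average ERD minima from a generated cohort (EEG chain).

    Returns per-condition grand-average ``(latency_s, amplitude_pct)``, the
    per-subject feature arrays, the grand-average curves and the time axis.
    """
    cohort = synthetic.generate_cohort(
        n_subjects, paradigm, effects, seed=seed,
        artifact_fraction=artifact_fraction, modalities=("eeg", "emg"),
    )
    curves: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    per_subject: dict[str, list[tuple[float, float]]] = {c: [] for c in CONDITIONS}
    times = None
    for session, truth in cohort:
        lap = laplacian(session, FOOT_DERIVATION)
        for cond in CONDITIONS:
            keep = _emg_keep(session, cond, window)
            ep = epoch(lap, session.events, session.sample_rate_hz, window, cond)
            ep = ep.subset(keep)
            curve = erd.erd_timecourse(
                ep, truth.beta_band_hz, reference_window, alpha=None
            )
            curves[cond].append(curve.values)
            per_subject[cond].append(erd.extract_minimum(curve))
            times = curve.times
    out = {
        "times": times,
        "curves": {},
        "minima": {},
        "per_subject": per_subject,
        "subject_curves": {c: np.vstack(curves[c]) for c in CONDITIONS},
    }
    for cond in CONDITIONS:
        ga = np.mean(curves[cond], axis=0)
        out["curves"][cond] = ga
        out["minima"][cond] = erd.extract_minimum(ga, times=times)
    return out


def recover_hr(
    seed: int,
    n_subjects: int = 16,
    paradigm: synthetic.ParadigmSpec | None = None,
    effects: synthetic.EffectSpec | None = None,
    artifact_fraction: float = 0.1,
    window: tuple[float, float] = DEFAULT_WINDOW,
    reference_window: tuple[float, float] = (-4.0, -2.0),
) -> dict:
    """Grand-average HR minima and hypothetical response (cardiac chain)."""
    cohort = synthetic.generate_cohort(
        n_subjects, paradigm, effects, seed=seed,
        artifact_fraction=artifact_fraction, modalities=("ecg", "emg"),
    )
    curves: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    hypo: list[np.ndarray] = []
    per_subject: dict[str, list[tuple[float, float]]] = {c: [] for c in CONDITIONS}
    times = None
    for session, truth in cohort:
        fs = session.sample_rate_hz
        beats = cardiac.detect_qrs(session.ecg, fs)
        hr = cardiac.hr_signal(beats, session.n_samples, fs)
        responses = {}
        for cond in CONDITIONS:
            keep = _emg_keep(session, cond, window)
            ep = cardiac.hr_epochs(hr, session.events, cond, window)
            ep = ep.subset(keep)
            keep_iqr, _ = rejection.hr_iqr_reject(ep, cond)
            responses[cond] = cardiac.hr_response(
                ep.subset(keep_iqr), reference_window=reference_window
            )
            curves[cond].append(responses[cond].values)
            per_subject[cond].append(cardiac.extract_hr_minimum(responses[cond]))
            times = responses[cond].times
        hypo.append(cardiac.hypothetical_hr(responses[GO], responses[NOGO]).values)
    out = {
        "times": times,
        "curves": {c: np.mean(curves[c], axis=0) for c in CONDITIONS},
        "hypothetical": np.mean(hypo, axis=0),
        "minima": {},
        "per_subject": per_subject,
        "subject_curves": {c: np.vstack(curves[c]) for c in CONDITIONS},
    }
    for cond in CONDITIONS:
        out["minima"][cond] = erd.extract_minimum(out["curves"][cond], times=times)
    return out


def qrs_fidelity(
    seed: int,
    duration_s: float = 300.0,
    snr_db: float | None = 10.0,
    effects: synthetic.EffectSpec | None = None,
) -> dict:
    """Detector sensitivity and timing error against generator ground truth."""
    import pandas as pd

    effects = effects or synthetic.EffectSpec()
    fs = 250.0
    n = int(duration_s * fs)
    ev = pd.DataFrame({"onset_sample": [n - 1], "label": [GO]})
    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)))
    ecg, truth, _ = synthetic.generate_ecg(ev, effects, rng, n_samples=n)
    if snr_db is not None:
        noise = np.sqrt(np.mean(ecg**2)) / 10 ** (snr_db / 20)
        ecg = ecg + noise * rng.standard_normal(n)
    beats = cardiac.detect_qrs(ecg, fs)
    core = truth[(truth > 2.0) & (truth < duration_s - 2.0)]
    errs = []
    hits = 0
    for t in core:
        d = np.abs(beats.times - t)
        i = int(np.argmin(d))
        if d[i] <= 0.05:
            hits += 1
            errs.append(d[i])
    return {
        "sensitivity": hits / core.size,
        "median_error_ms": 1000.0 * float(np.median(errs)),
        "max_error_ms": 1000.0 * float(np.max(errs)),
        "n_beats": int(core.size),
    }


def bootstrap_false_positive_rate(
    seed: int,
    n_cohorts: int = 1000,
    n_subjects: int = 16,
    n_samples: int = 50,
    n_resamples: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Per-sample type-I error of the t-percentile bootstrap under the null."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 88)))
    flagged = 0
    total = 0
    for _ in range(n_cohorts):
        curves = rng.standard_normal((n_subjects, n_samples))
        band = stats.tpercentile_bootstrap(curves, alpha, n_resamples, rng)
        flagged += int(band.significant.sum())
        total += n_samples
    return {"rate": flagged / total, "n": total}
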