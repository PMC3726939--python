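"""Synthetic EEG/ECG/EMG sessions with planted, analytically known effects.

The generator emulates a cue-paced go/nogo foot motor-imagery session:
3 runs × 40 trials, 50 % go probability, inter-cue interval uniform on
11–14 s, 250 Hz sampling.  Planted effects follow the reported group
structure: an early beta-band ERD dip near 400 ms (≈ −40 % go / −32 % nogo),
a go-condition peri-imagery ERD and delayed rebound, a nogo rebound (ERS)
peaking ≈ 1 s, a cue-locked heart-rate deceleration (≈ −1 % go / −1.9 % nogo
near 650 ms) with a go acceleration bump near 2 s, slow background HR
fluctuations near 0.1 and 0.25 Hz, and EMG bursts in designated artifact
trials.

Everything is driven by analytic truth models (:func:`erd_truth_curve`,
:func:`hr_truth_curve`) so the planted depths/latencies are exact by
construction:

* EEG: each channel is pink (1/f) background noise — a component shared
  within a Laplacian group plus an independent component — carrying a
  beta-band oscillation whose amplitude envelope is ``sqrt(1 + g(t)/100)``,
  with ``g`` the percent band-power profile.  The oscillation appears on the
  four neighbour channels at half amplitude (common mode), so the Laplacian
  derivation keeps the modulation while cancelling the shared noise.
* ECG: beats are laid down by integral-pulse frequency modulation (IPFM) of
  the planted instantaneous-rate signal, each beat rendered as a fixed
  Mexican-hat (Ricker) template ≈ 80 ms wide; the true beat times are part of
  the ground truth.
* EMG: bounded (uniform-noise) positive baseline resembling the integrated
  EMG channel; flagged trials get a post-cue burst whose peak sits exactly at
  ``rest mean + 6·SD`` of that trial's own 5 s pre-cue window, guaranteed
  above both rejection thresholds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .montage import DEFAULT_MONTAGE, EEG_CHANNELS, FOOT_DERIVATION
from .session import DEFAULT_WINDOW, GO, NOGO, Session

# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParadigmSpec:
    """Trial structure and timing of the cue-paced go/nogo paradigm."""

    n_runs: int = 3
    trials_per_run: int = 40
    p_go: float = 0.5
    cue_duration_s: float = 2.0
    inter_cue_min_s: float = 11.0
    inter_cue_max_s: float = 14.0
    sample_rate_hz: float = 250.0
    lead_in_s: float = 6.0   # quiet time before the first inter-cue gap
    tail_s: float = 8.0      # quiet time after the last cue

    def __post_init__(self) -> None:
        if self.p_go < 0 or self.p_go > 1:
            raise ParameterError("p_go must lie in [0, 1]")
        if self.inter_cue_min_s > self.inter_cue_max_s:
            raise ParameterError("inter_cue_min_s must be <= inter_cue_max_s")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise ParameterError("n_runs and trials_per_run must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect sizes; depths signed percent (ERD < 0, ERS > 0).

    Depth/latency defaults are the reported group means; shape widths are the
    generator's own smooth-bump model (see docs/methods.md).
    """

    beta_band_hz: tuple[float, float] = (20.0, 28.0)
    erd_early_depth_go: float = -39.82
    erd_early_depth_nogo: float = -32.00
    erd_early_latency_go_s: float = 0.471
    erd_early_latency_nogo_s: float = 0.397
    erd_early_width_s: float = 0.26
    peri_imagery_depth: float = -25.0
    peri_imagery_span_s: tuple[float, float] = (0.9, 2.5)
    rebound_gain: float = 30.0
    rebound_latency_nogo_s: float = 1.0
    rebound_width_s: float = 0.22
    post_imagery_rebound_latency_s: float = 3.5
    hr_baseline_bpm: float = 88.0
    hr_decel_go: float = -1.00
    hr_decel_nogo: float = -1.94
    hr_decel_latency_go_s: float = 0.640
    hr_decel_latency_nogo_s: float = 0.652
    hr_decel_width_left_s: float = 0.33
    hr_decel_width_right_s: float = 0.45
    hr_decel_pedestal_frac: float = 0.80
    hr_decel_pedestal_width_s: float = 1.3
    hr_accel_go: float = 1.5
    hr_accel_latency_s: float = 2.0
    hr_accel_width_left_s: float = 0.4
    hr_accel_width_right_s: float = 0.8
    slow_hr_amp: float = 1.5  # percent, per sinusoidal component
    slow_hr_freqs_hz: tuple[float, float] = (0.1, 0.25)
    rr_jitter_ms: float = 0.0   # optional white beat-timing jitter (off: real short-term HRV is smooth)
    subject_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.beta_band_hz
        if not (8.0 <= lo < hi <= 45.0):
            raise ParameterError("beta_band_hz must lie within 8–45 Hz")
        for name in ("erd_early_depth_go", "erd_early_depth_nogo",
                     "hr_decel_go", "hr_decel_nogo"):
            if getattr(self, name) > 0:
                raise ParameterError(f"{name} is a deceleration/ERD: must be <= 0")
        for name in ("erd_early_latency_go_s", "erd_early_latency_nogo_s",
                     "hr_decel_latency_go_s", "hr_decel_latency_nogo_s"):
            v = getattr(self, name)
            if not (0.0 < v <= DEFAULT_WINDOW[1]):
                raise ParameterError(f"{name} must lie in the post-cue window")

    @property
    def carrier_hz(self) -> float:
        return 0.5 * (self.beta_band_hz[0] + self.beta_band_hz[1])


#: nominal between-subject SDs multiplied by ``EffectSpec.subject_sd_scale``
SUBJECT_SD = {
    "erd_depth_pp": 4.0,
    "erd_latency_s": 0.03,
    "hr_depth_pp": 0.15,
    "hr_latency_s": 0.05,
    "band_shift_bins": 0.5,  # SD of the (rounded) 2-Hz band shift
}

# fixed signal amplitudes (microvolts / millivolts), see docs/methods.md
BETA_AMP_UV = 10.0
OTHER_GROUP_BETA_AMP_UV = 5.0
NEIGHBOUR_BETA_GAIN = 0.5
PINK_SHARED_UV = 3.0
PINK_INDEP_UV = 1.0
QRS_SIGMA_S = 0.02
QRS_AMP_MV = 1.0
EMG_BASELINE = 1.0
EMG_BURST_K = 6.0


@dataclass
class GroundTruth:
    """Everything a recovery test needs to know about one generated session."""

    labels: np.ndarray                 # per-trial condition labels
    artifact_flags: np.ndarray         # per-trial planted EMG-burst flags
    beta_band_hz: tuple[float, float]  # the subject's true reactive band
    epoch_times: np.ndarray            # epoch time axis, seconds vs. cue
    erd_truth: dict[str, np.ndarray]   # condition -> percent band-power curve
    hr_truth: dict[str, np.ndarray]    # condition -> percent HR curve
    beat_times: np.ndarray | None      # true beat times, seconds
    rate_bpm: np.ndarray | None        # planted instantaneous rate, session clock
    effects: EffectSpec | None = None  # the subject-level effect parameters

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "labels": [str(x) for x in self.labels],
            "artifact_flags": [bool(x) for x in self.artifact_flags],
            "beta_band_hz": list(self.beta_band_hz),
            "epoch_times": self.epoch_times.tolist(),
            "erd_truth": {k: v.tolist() for k, v in self.erd_truth.items()},
            "hr_truth": {k: v.tolist() for k, v in self.hr_truth.items()},
            "beat_times": None if self.beat_times is None else self.beat_times.tolist(),
            "effects": None if self.effects is None else dataclasses.asdict(self.effects),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


# ---------------------------------------------------------------------------
# analytic truth models
# ---------------------------------------------------------------------------


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _agauss(t: np.ndarray, mu: float, sl: float, sr: float) -> np.ndarray:
    """Asymmetric Gaussian bump (different left/right widths), peak 1 at ``mu``."""
    t = np.asarray(t, dtype=float)
    sigma = np.where(t < mu, sl, sr)
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _decel_shape(t: np.ndarray, mu: float, effects: "EffectSpec") -> np.ndarray:
    """Unit-depth deceleration: sharp causal core on a broad slow pedestal.

    The core (asymmetric Gaussian) anchors the latency of the minimum; the
    pedestal — a slow symmetric component peaking at the same latency, akin
    to the documented anticipatory/slow HR deceleration — carries depth that
    survives beat-to-beat sampling of the rate signal.  Both components peak
    at 1, so the planted value at ``mu`` equals the requested depth exactly.
    """
    f = effects.hr_decel_pedestal_frac
    core = _agauss(t, mu, effects.hr_decel_width_left_s, effects.hr_decel_width_right_s)
    # gate the slow pedestal so the 2-4 s pre-cue reference stays clean: the
    # anticipatory component develops only in the last ~1.5 s before the cue
    gate = _sigmoid((t + 1.4) / 0.12)
    pedestal = _gauss(t, mu, effects.hr_decel_pedestal_width_s) * gate
    return (1.0 - f) * core + f * pedestal


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def _peri_profile(t: np.ndarray, effects: EffectSpec) -> np.ndarray:
    a, b = effects.peri_imagery_span_s
    return effects.peri_imagery_depth * (
        _sigmoid((t - a) / 0.12) - _sigmoid((t - b) / 0.25)
    )


def _onset_gate(t: np.ndarray) -> np.ndarray:
    """Causal onset of cortical responses: ~100 ms visuomotor delay."""
    return _sigmoid((np.asarray(t, dtype=float) - 0.10) / 0.035)


GO_EXTRA_WIDTH_S = 0.20
GO_EXTRA_ONSET_S = 0.25


def _common_dip_amp(effects: EffectSpec) -> float:
    """Shared early-dip amplitude, set by the nogo planted depth."""
    lat = effects.erd_early_latency_nogo_s
    reb = effects.rebound_gain * float(
        _gauss(np.asarray([lat]), effects.rebound_latency_nogo_s,
               effects.rebound_width_s)[0]
    )
    return (
        effects.erd_early_depth_nogo / float(_onset_gate(np.asarray([lat]))[0]) - reb
    )


def _go_base(effects: EffectSpec, t: np.ndarray) -> np.ndarray:
    """Go-condition profile without the imagery-specific early component."""
    return (
        _common_dip_amp(effects)
        * _gauss(t, effects.erd_early_latency_nogo_s, effects.erd_early_width_s)
        + _peri_profile(t, effects)
        + effects.rebound_gain
        * _gauss(t, effects.post_imagery_rebound_latency_s, 0.5)
    )


def _go_extra_params(effects: EffectSpec) -> tuple[float, float]:
    """Amplitude and centre of the go-specific early-ERD component.

    Both conditions share one automatic (orienting) early dip with the nogo
    parameters; executing the imagery adds a later component.  Its amplitude
    and centre are solved so that the go curve passes through the planted go
    depth at the planted go latency with zero slope — i.e. the go early
    minimum sits exactly on the planted coordinates.
    """
    import scipy.optimize

    L = effects.erd_early_latency_go_s
    target = effects.erd_early_depth_go / float(_onset_gate(np.asarray([L]))[0])
    base_L = float(_go_base(effects, np.asarray([L]))[0])
    if abs(target - base_L) < 1e-12:
        return 0.0, L

    def extra(tv, amp, mu):
        return amp * _gauss(tv, mu, GO_EXTRA_WIDTH_S) * _sigmoid(
            (tv - GO_EXTRA_ONSET_S) / 0.05
        )

    def equations(x):
        amp, mu = x
        h = 1e-4
        tv = np.asarray([L - h, L, L + h])
        f = _go_base(effects, tv) + extra(tv, amp, mu)
        return [f[1] - target, (f[2] - f[0]) / (2 * h)]

    sol, _, ok, _ = scipy.optimize.fsolve(
        equations, x0=[target - base_L, L + 0.08], full_output=True
    )
    amp, mu = float(sol[0]), float(sol[1])
    if ok != 1 or not (effects.erd_early_latency_nogo_s < mu < 1.5):
        return target - base_L, L  # fall back to a peak pinned at the latency
    return amp, mu


def erd_truth_curve(
    effects: EffectSpec, condition: str, times: np.ndarray, mode: str = "mi"
) -> np.ndarray:
    """Planted percent band-power change ``g(t)`` relative to cue onset.

    Both conditions carry the same automatic early dip (planted with the
    nogo depth/latency); the go condition adds an imagery-preparation
    component solved so its early minimum lands exactly on the planted go
    depth/latency, plus the peri-imagery ERD and the delayed post-imagery
    rebound.  The nogo condition instead rebounds (ERS) shortly after the
    dip.  Everything is gated to start ~100 ms after the cue.
    """
    t = np.asarray(times, dtype=float)
    gate = _onset_gate(t)
    se = effects.erd_early_width_s
    if condition == GO and mode == "me":
        # execution block: movement-period ERD and a strong, earlier rebound
        lat, depth = effects.erd_early_latency_go_s, effects.erd_early_depth_go
        base = effects.peri_imagery_depth * (
            _sigmoid((t - 0.2) / 0.1) - _sigmoid((t - 1.0) / 0.2)
        ) + 3.0 * effects.rebound_gain * _gauss(t, 1.6, 0.35)
        base_lat = float(
            np.interp(lat, t, base) if t.size > 1 else base[0]
        )
        tb = np.asarray([lat])
        base_lat = effects.peri_imagery_depth * float(
            (_sigmoid((tb - 0.2) / 0.1) - _sigmoid((tb - 1.0) / 0.2))[0]
        ) + 3.0 * effects.rebound_gain * float(_gauss(tb, 1.6, 0.35)[0])
        amp = depth / float(_onset_gate(tb)[0]) - base_lat
        return (base + amp * _gauss(t, lat, se)) * gate
    if condition == GO:
        amp_x, mu_x = _go_extra_params(effects)
        g = _go_base(effects, t) + amp_x * _gauss(t, mu_x, GO_EXTRA_WIDTH_S) * _sigmoid(
            (t - GO_EXTRA_ONSET_S) / 0.05
        )
    elif condition == NOGO:
        g = _common_dip_amp(effects) * _gauss(
            t, effects.erd_early_latency_nogo_s, se
        ) + effects.rebound_gain * _gauss(
            t, effects.rebound_latency_nogo_s, effects.rebound_width_s
        )
    else:
        raise ParameterError(f"unknown condition {condition!r}")
    return g * gate


def hr_truth_curve(effects: EffectSpec, condition: str, times: np.ndarray) -> np.ndarray:
    """Planted percent heart-rate change relative to cue onset."""
    t = np.asarray(times, dtype=float)
    h = np.zeros_like(t)
    if condition == GO:
        lat, depth = effects.hr_decel_latency_go_s, effects.hr_decel_go
        accel = effects.hr_accel_go * _agauss(
            t, effects.hr_accel_latency_s,
            effects.hr_accel_width_left_s, effects.hr_accel_width_right_s,
        )
        accel_at_lat = effects.hr_accel_go * float(
            _agauss(
                np.asarray([lat]), effects.hr_accel_latency_s,
                effects.hr_accel_width_left_s, effects.hr_accel_width_right_s,
            )[0]
        )
        h = h + accel
    elif condition == NOGO:
        lat, depth = effects.hr_decel_latency_nogo_s, effects.hr_decel_nogo
        accel_at_lat = 0.0
    else:
        raise ParameterError(f"unknown condition {condition!r}")
    shape_at_lat = float(_decel_shape(np.asarray([lat]), lat, effects)[0])
    amp = (depth - accel_at_lat) / shape_at_lat
    h = h + amp * _decel_shape(t, lat, effects)
    return h


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_events(paradigm: ParadigmSpec, seed: int | np.random.Generator) -> pd.DataFrame:
    """Cue onsets and go/nogo labels for one session.

    Successive onset gaps are i.i.d. uniform on
    ``[inter_cue_min_s, inter_cue_max_s]``; labels are i.i.d. Bernoulli(p_go).
    """
    rng = np.random.default_rng(seed)
    n = paradigm.n_trials
    gaps = rng.uniform(paradigm.inter_cue_min_s, paradigm.inter_cue_max_s, size=n)
    onsets_s = paradigm.lead_in_s + np.cumsum(gaps)
    labels = np.where(rng.random(n) < paradigm.p_go, GO, NOGO)
    onsets = np.round(onsets_s * paradigm.sample_rate_hz).astype(int)
    return pd.DataFrame({"onset_sample": onsets, "label": labels})


def session_length_samples(events: pd.DataFrame, paradigm: ParadigmSpec) -> int:
    return int(events["onset_sample"].max() + paradigm.tail_s * paradigm.sample_rate_hz)


def _pink_noise(n: int, fs: float, rng: np.random.Generator, rows: int = 1) -> np.ndarray:
    """Unit-variance 1/f noise, flat below 1 Hz, zero below 0.1 Hz.

    Returns shape ``(rows, n)``; rows are independent and FFT-batched.
    """
    import scipy.fft

    nfft = scipy.fft.next_fast_len(n)  # arbitrary n can be a pathological FFT size
    white = rng.standard_normal((rows, nfft))
    spec = scipy.fft.rfft(white, axis=-1)
    f = scipy.fft.rfftfreq(nfft, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))
    scale[f < 0.1] = 0.0
    x = scipy.fft.irfft(spec * scale[None, :], n=nfft, axis=-1)[:, :n]
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return x / s


def _event_profile(
    n: int,
    fs: float,
    events: pd.DataFrame,
    per_condition: dict[str, np.ndarray],
    offsets: np.ndarray,
) -> np.ndarray:
    """Sum per-event response snippets onto the session time grid."""
    out = np.zeros(n)
    for onset, label in zip(events["onset_sample"], events["label"]):
        idx = onset + offsets
        ok = (idx >= 0) & (idx < n)
        out[idx[ok]] += per_condition[label][ok]
    return out


def generate_eeg(
    events: pd.DataFrame,
    effects: EffectSpec,
    seed: int | np.random.Generator,
    n_samples: int | None = None,
    sample_rate_hz: float = 250.0,
    mode: str = "mi",
) -> np.ndarray:
    """15-channel continuous EEG with the planted condition-specific envelope.

    The band-power profile ``g(t)`` enters as an amplitude envelope
    ``sqrt(1 + g/100)`` on the beta oscillation of the foot-area (Cz) group,
    so the modulated/unmodulated band-power ratio in the dip equals
    ``1 + depth/100`` by construction.
    """
    rng = np.random.default_rng(seed)
    fs = float(sample_rate_hz)
    if n_samples is None:
        n_samples = int(events["onset_sample"].max() + 8.0 * fs)
    fc = effects.carrier_hz
    if not (0.5 < fc < 100.0):
        raise ParameterError(f"beta carrier {fc} Hz outside the 0.5–100 Hz passband")

    t = np.arange(n_samples) / fs
    # per-event envelope snippets on [-2, +6.5] s around the cue
    offsets = np.arange(int(-2.0 * fs), int(6.5 * fs) + 1)
    snippet_t = offsets / fs
    profiles = {
        c: erd_truth_curve(effects, c, snippet_t, mode=mode) for c in (GO, NOGO)
    }
    g = _event_profile(n_samples, fs, events, profiles, offsets)
    envelope = np.sqrt(np.clip(1.0 + g / 100.0, 0.01, None))

    eeg = np.empty((len(EEG_CHANNELS), n_samples))
    row = 0
    for name, (centre, neighbours) in DEFAULT_MONTAGE.items():
        group = (centre, *neighbours)
        noise = _pink_noise(n_samples, fs, rng, rows=1 + len(group))
        shared = PINK_SHARED_UV * noise[0]
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(2 * np.pi * fc * t + phase)
        if name == FOOT_DERIVATION:
            osc = BETA_AMP_UV * envelope * carrier
        else:
            osc = OTHER_GROUP_BETA_AMP_UV * carrier
        for k, ch in enumerate(group):
            gain = 1.0 if ch == centre else NEIGHBOUR_BETA_GAIN
            eeg[row] = shared + PINK_INDEP_UV * noise[1 + k] + gain * osc
            row += 1
    return eeg


def generate_ecg(
    events: pd.DataFrame,
    effects: EffectSpec,
    seed: int | np.random.Generator,
    n_samples: int | None = None,
    sample_rate_hz: float = 250.0,
    template_amplitude_mv: float = QRS_AMP_MV,
    noise_rms_mv: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-channel ECG, true beat times, and the planted rate signal.

    Beats come from integral-pulse frequency modulation of the instantaneous
    rate ``r(t) = baseline·(1 + slow fluctuations + cue-locked response)``;
    each beat is rendered as a Ricker wavelet.  Returns
    ``(ecg_mv, beat_times_s, rate_bpm)``.
    """
    rng = np.random.default_rng(seed)
    fs = float(sample_rate_hz)
    if n_samples is None:
        n_samples = int(events["onset_sample"].max() + 8.0 * fs)
    if not (40.0 <= effects.hr_baseline_bpm <= 120.0):
        raise ParameterError("hr_baseline_bpm must lie in [40, 120]")

    t = np.arange(n_samples) / fs
    f1, f2 = effects.slow_hr_freqs_hz
    slow = (effects.slow_hr_amp / 100.0) * (
        np.sin(2 * np.pi * f1 * t + rng.uniform(0, 2 * np.pi))
        + np.sin(2 * np.pi * f2 * t + rng.uniform(0, 2 * np.pi))
    )
    offsets = np.arange(0, int(6.5 * fs) + 1)
    snippet_t = offsets / fs
    profiles = {c: hr_truth_curve(effects, c, snippet_t) for c in (GO, NOGO)}
    resp = _event_profile(n_samples, fs, events, profiles, offsets) / 100.0
    rate_bpm = effects.hr_baseline_bpm * (1.0 + slow + resp)
    if np.any(rate_bpm <= 0):
        raise ParameterError("planted rate signal is non-positive somewhere")

    # IPFM: beats where the integrated instantaneous frequency crosses integers
    freq_hz = rate_bpm / 60.0
    phi = np.concatenate([[0.0], np.cumsum(0.5 * (freq_hz[1:] + freq_hz[:-1]))]) / fs
    ks = np.arange(1, int(np.floor(phi[-1])) + 1)
    beat_times = np.interp(ks, phi, t)
    if effects.rr_jitter_ms > 0:
        # beat-scale timing variability on top of the IPFM times: real R-R
        # series carry white jitter that dominates the |dHR/dt| floor
        beat_times = beat_times + rng.normal(
            0.0, effects.rr_jitter_ms / 1000.0, size=beat_times.size
        )
        beat_times = np.sort(beat_times)

    ecg = np.zeros(n_samples)
    half = int(round(3 * QRS_SIGMA_S * fs))
    rel = np.arange(-half, half + 1)
    for bt in beat_times:
        centre = int(round(bt * fs))
        idx = centre + rel
        ok = (idx >= 0) & (idx < n_samples)
        tau = idx[ok] / fs - bt
        x2 = (tau / QRS_SIGMA_S) ** 2
        ecg[idx[ok]] += template_amplitude_mv * (1.0 - x2) * np.exp(-0.5 * x2)
    if noise_rms_mv > 0:
        ecg = ecg + noise_rms_mv * rng.standard_normal(n_samples)
    return ecg, beat_times, rate_bpm


def generate_emg(
    events: pd.DataFrame,
    artifact_fraction: float,
    seed: int | np.random.Generator,
    n_samples: int | None = None,
    sample_rate_hz: float = 250.0,
    burst_k: float = EMG_BURST_K,
) -> tuple[np.ndarray, np.ndarray]:
    """2-channel integrated-EMG-like signal and per-trial artifact flags.

    The baseline is positive noise with *bounded* deviation (< 2.5 SD), so
    clean trials can never trip the mean+3·SD rule; flagged trials get a
    post-cue burst on the left leg whose peak equals exactly
    ``rest_mean + burst_k · rest_SD`` of that trial's own 5 s pre-cue window.
    """
    if not (0.0 <= artifact_fraction <= 1.0):
        raise ParameterError("artifact_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fs = float(sample_rate_hz)
    if n_samples is None:
        n_samples = int(events["onset_sample"].max() + 8.0 * fs)

    # average of two uniforms: max deviation 2.45 SD from the mean
    emg = EMG_BASELINE + 0.2 * 0.5 * (
        rng.random((2, n_samples)) + rng.random((2, n_samples))
    )
    flags = rng.random(len(events)) < artifact_fraction

    rest = int(5.0 * fs)
    b0, b1 = int(0.3 * fs), int(1.2 * fs)  # burst window, seconds post-cue
    burst_shape = np.sin(np.pi * np.arange(b1 - b0) / (b1 - b0))
    burst_shape[(b1 - b0) // 2] = 1.0  # peak sample hits the target exactly
    for (onset, flagged) in zip(events["onset_sample"], flags):
        if not flagged or onset - rest < 0 or onset + b1 >= n_samples:
            continue
        rest_sig = emg[0, onset - rest : onset]
        mu, sd = rest_sig.mean(), rest_sig.std()
        peak = mu + burst_k * sd
        seg = slice(onset + b0, onset + b1)
        emg[0, seg] = np.maximum(emg[0, seg], peak * burst_shape)
    return emg, flags


def generate_session(
    paradigm: ParadigmSpec | None = None,
    effects: EffectSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    mode: str = "mi",
    artifact_fraction: float = 0.1,
    modalities: tuple[str, ...] = ("eeg", "ecg", "emg"),
) -> tuple[Session, GroundTruth]:
    """Generate one full session plus its ground truth.

    ``mode='me'`` produces a motor-execution block (strong beta rebound) used
    for subject-specific band selection.  ``modalities`` restricts which
    signals are synthesised (omitted ones are zero-filled), which the
    recovery harness uses to keep single-modality studies fast.
    """
    paradigm = paradigm or ParadigmSpec()
    effects = effects or EffectSpec()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_ev, s_eeg, s_ecg, s_emg = ss.spawn(4)

    events = generate_events(paradigm, np.random.default_rng(s_ev))
    fs = paradigm.sample_rate_hz
    n = session_length_samples(events, paradigm)

    if "eeg" in modalities:
        eeg = generate_eeg(events, effects, np.random.default_rng(s_eeg), n, fs, mode=mode)
    else:
        eeg = np.zeros((len(EEG_CHANNELS), n))
    if "ecg" in modalities:
        ecg, beat_times, rate_bpm = generate_ecg(
            events, effects, np.random.default_rng(s_ecg), n, fs
        )
    else:
        ecg, beat_times, rate_bpm = np.zeros(n), None, None
    if "emg" in modalities:
        emg, flags = generate_emg(
            events, artifact_fraction, np.random.default_rng(s_emg), n, fs
        )
    else:
        emg, flags = np.zeros((2, n)), np.zeros(len(events), dtype=bool)

    session = Session(
        eeg=eeg,
        emg=emg,
        ecg=ecg,
        sample_rate_hz=fs,
        events=events,
        meta={"mode": mode, "seed": str(ss.entropy)},
    )
    w0, w1 = DEFAULT_WINDOW
    epoch_times = np.arange(int(w0 * fs), int(w1 * fs) + 1) / fs
    truth = GroundTruth(
        labels=events["label"].to_numpy(),
        artifact_flags=flags,
        beta_band_hz=effects.beta_band_hz,
        epoch_times=epoch_times,
        erd_truth={
            c: erd_truth_curve(effects, c, epoch_times, mode=mode) for c in (GO, NOGO)
        },
        hr_truth={c: hr_truth_curve(effects, c, epoch_times) for c in (GO, NOGO)},
        beat_times=beat_times,
        rate_bpm=rate_bpm,
        effects=effects,
    )
    return session, truth


def _truncnorm(rng, mean, sd, lo, hi):
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def perturb_effects(
    effects: EffectSpec, rng: np.random.Generator
) -> EffectSpec:
    """Draw one subject's effect parameters around the population spec."""
    s = effects.subject_sd_scale
    shift_bins = int(round(rng.normal(0.0, SUBJECT_SD["band_shift_bins"] * s)))
    lo, hi = effects.beta_band_hz
    lo2, hi2 = lo + 2 * shift_bins, hi + 2 * shift_bins
    if lo2 < 8.0 or hi2 > 44.0:
        lo2, hi2 = lo, hi
    return dataclasses.replace(
        effects,
        beta_band_hz=(lo2, hi2),
        erd_early_depth_go=_truncnorm(
            rng, effects.erd_early_depth_go, SUBJECT_SD["erd_depth_pp"] * s, -85.0, -5.0
        ),
        erd_early_depth_nogo=_truncnorm(
            rng, effects.erd_early_depth_nogo, SUBJECT_SD["erd_depth_pp"] * s, -85.0, -5.0
        ),
        erd_early_latency_go_s=_truncnorm(
            rng, effects.erd_early_latency_go_s, SUBJECT_SD["erd_latency_s"] * s, 0.2, 0.9
        ),
        erd_early_latency_nogo_s=_truncnorm(
            rng, effects.erd_early_latency_nogo_s, SUBJECT_SD["erd_latency_s"] * s, 0.2, 0.9
        ),
        hr_decel_go=_truncnorm(
            rng, effects.hr_decel_go, SUBJECT_SD["hr_depth_pp"] * s, -6.0, -0.2
        ),
        hr_decel_nogo=_truncnorm(
            rng, effects.hr_decel_nogo, SUBJECT_SD["hr_depth_pp"] * s, -6.0, -0.2
        ),
        hr_decel_latency_go_s=_truncnorm(
            rng, effects.hr_decel_latency_go_s, SUBJECT_SD["hr_latency_s"] * s, 0.3, 0.9
        ),
        hr_decel_latency_nogo_s=_truncnorm(
            rng, effects.hr_decel_latency_nogo_s, SUBJECT_SD["hr_latency_s"] * s, 0.3, 0.9
        ),
    )


def generate_cohort(
    n_subjects: int,
    paradigm: ParadigmSpec | None = None,
    effects: EffectSpec | None = None,
    seed: int = 0,
    mode: str = "mi",
    artifact_fraction: float = 0.1,
    modalities: tuple[str, ...] = ("eeg", "ecg", "emg"),
) -> list[tuple[Session, GroundTruth]]:
    """Generate ``n_subjects`` independent sessions with per-subject effects.

    Subject effect values are Gaussian perturbations of the population
    :class:`EffectSpec`, truncated to valid ranges, with spread controlled by
    ``effects.subject_sd_scale``.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    paradigm = paradigm or ParadigmSpec()
    effects = effects or EffectSpec()
    root = np.random.SeedSequence(seed)
    out = []
    for child in root.spawn(n_subjects):
        rng = np.random.default_rng(child.spawn(1)[0])
        subj_effects = perturb_effects(effects, rng)
        out.append(
            generate_session(
                paradigm,
                subj_effects,
                seed=child,
                mode=mode,
                artifact_fraction=artifact_fraction,
                modalities=modalities,
            )
        )
    return out
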