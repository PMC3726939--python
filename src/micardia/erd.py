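"""ERD/ERS quantification by the inter-trial variance method.

Pipeline per frequency band: zero-phase 5th-order Butterworth band-pass →
subtract the per-sample ensemble average across trials (removes phase-locked
evoked components) → square → average across trials → 250 ms centred moving
average → percent change against the mean smoothed power in a pre-cue
reference interval (default 2–4 s before the cue).  Negative values are ERD
(desynchronisation, activation), positive values ERS (synchronisation).

Significance of per-sample power values uses a Box-Cox transform toward
normality estimated on the pooled reference-window power, with a t-based
interval for the cross-trial reference mean.  Time–frequency maps apply the
single-band estimator over 2-Hz bins between 8 and 45 Hz.  Subject-specific
reactive bands are selected by Cohen's-kappa discriminability between the
post-movement beta rebound and the reference interval on motor-execution
trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.special
import scipy.stats

from .errors import InsufficientDataError, ParameterError
from .session import EpochSet

DEFAULT_REFERENCE = (-4.0, -2.0)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ErdCurve:
    """Single-band percent power change with optional significance mask."""

    times: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    reference_window: tuple[float, float]
    significant: np.ndarray | None = None
    alpha: float | None = None
    n_trials: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < -100.0 - 1e-9):
            raise ParameterError("percent power change below -100% is impossible")

    def to_frame(self):
        """Tidy (time, value, significant) table for TSV export."""
        import pandas as pd

        sig = self.significant if self.significant is not None else np.zeros(
            self.values.size, dtype=bool
        )
        return pd.DataFrame(
            {"time_s": self.times, "value_pct": self.values,
             "significant": sig.astype(int)}
        )


@dataclass
class ErdMap:
    """Time–frequency percent power change over contiguous 2-Hz bands."""

    times: np.ndarray
    bands: list[tuple[float, float]]
    values: np.ndarray  # (n_bands, n_times)
    significant: np.ndarray  # same shape, bool
    reference_window: tuple[float, float]
    alpha: float

    def masked(self) -> np.ndarray:
        """Values with non-significant cells set to NaN (rendering rule)."""
        out = self.values.copy()
        out[~self.significant] = np.nan
        return out

    def to_frame(self):
        """Long-format (band_low, band_high, time, value, significant) table."""
        import pandas as pd

        rows = []
        for (lo, hi), vals, sig in zip(self.bands, self.values, self.significant):
            rows.append(pd.DataFrame(
                {"band_low_hz": lo, "band_high_hz": hi, "time_s": self.times,
                 "value_pct": vals, "significant": sig.astype(int)}
            ))
        return pd.concat(rows, ignore_index=True)


@dataclass
class BandSelection:
    band: tuple[float, float]
    kappa: float
    scores: dict[tuple[float, float], float]
    rebound_window: tuple[float, float]
    reference_window: tuple[float, float]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def bandpass(
    data: np.ndarray, band: tuple[float, float], sample_rate_hz: float, order: int = 5
) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth band-pass along the last axis.

    Forward–backward application doubles the effective order but preserves
    latencies, which matter here because peak latencies are reported features.
    """
    lo, hi = band
    nyq = sample_rate_hz / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ParameterError(f"band {band} must satisfy 0 < lo < hi < Nyquist ({nyq})")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate_hz, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def moving_average(x: np.ndarray, n_samples: int) -> np.ndarray:
    """Centred moving average along the last axis; edges use the partial window."""
    if n_samples <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(n_samples)
    x = np.asarray(x, dtype=float)
    counts = np.convolve(np.ones(x.shape[-1]), kernel, mode="same")
    return np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same") / counts, -1, x
    )


def _smoothed_power(
    epochs: EpochSet, band, smooth_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial smoothed induced power and the trial-averaged smoothed power."""
    trials = bandpass(epochs.data, band, epochs.sample_rate_hz)
    induced = trials - trials.mean(axis=0, keepdims=True)
    power = induced**2
    w = max(1, int(round(smooth_s * epochs.sample_rate_hz)))
    power_s = moving_average(power, w)
    avg_s = moving_average(power.mean(axis=0), w)
    return power_s, avg_s


def erd_timecourse(
    epochs: EpochSet,
    band: tuple[float, float],
    reference_window: tuple[float, float] = DEFAULT_REFERENCE,
    smooth_s: float = 0.25,
    alpha: float | None = 0.05,
) -> ErdCurve:
    """Percent band-power change over time for one epoch set.

    ``100 · (P(t) − P̄_ref) / P̄_ref`` with ``P̄_ref`` the mean smoothed power
    over the reference window (half-open ``[a, b)``).
    """
    if epochs.n_trials < 2:
        raise InsufficientDataError("inter-trial variance needs >= 2 trials")
    ref_mask = epochs.time_mask(reference_window)
    if not ref_mask.any():
        raise ParameterError(f"reference window {reference_window} outside the epoch")
    power_s, avg_s = _smoothed_power(epochs, band, smooth_s)
    p_ref = avg_s[ref_mask].mean()
    values = 100.0 * (avg_s - p_ref) / p_ref
    sig = None
    if alpha is not None:
        sig = boxcox_significance(power_s, epochs.times, reference_window, alpha)
    return ErdCurve(
        times=epochs.times,
        values=values,
        band=tuple(band),
        reference_window=tuple(reference_window),
        significant=sig,
        alpha=alpha,
        n_trials=epochs.n_trials,
    )


def boxcox_significance(
    power_trials: np.ndarray,
    times: np.ndarray,
    reference_window: tuple[float, float],
    alpha: float = 0.05,
) -> np.ndarray:
    """Per-sample significance of power deviations from the reference level.

    λ is estimated by profile maximum likelihood on the pooled
    reference-window power and applied everywhere.  The null interval for a
    cross-trial mean is ``μ̂ ± t_{1−α/2, n−1} · s/√n`` where ``s²`` is the
    across-trial variance at individual reference samples pooled over the
    window (this is the variance a single time sample's mean actually has
    under the null; see docs/methods.md).  A sample is significant iff its
    transformed cross-trial mean falls outside the interval.
    """
    power_trials = np.asarray(power_trials, dtype=float)
    if np.any(power_trials <= 0):
        raise ParameterError("Box-Cox requires strictly positive power values")
    n = power_trials.shape[0]
    a, b = reference_window
    t = np.asarray(times)
    ref_mask = (t >= a - 1e-9) & (t < b - 1e-9)
    ref = power_trials[:, ref_mask]
    if np.ptp(ref) == 0:
        lmbda = 1.0
    else:
        _, lmbda = scipy.stats.boxcox(ref.ravel())
    y = scipy.special.boxcox(power_trials, lmbda)
    y_ref = y[:, ref_mask]
    mu = y_ref.mean()
    s2 = y_ref.var(axis=0, ddof=1).mean()
    half = scipy.stats.t.ppf(1.0 - alpha / 2.0, df=n - 1) * np.sqrt(s2 / n)
    # guard against floating fuzz when the interval is (near) zero-width
    tol = 1e-9 * (1.0 + abs(mu))
    mean_t = y.mean(axis=0)
    return (mean_t < mu - half - tol) | (mean_t > mu + half + tol)


def make_bands(
    fmin: float = 8.0, fmax: float = 45.0, step: float = 2.0
) -> list[tuple[float, float]]:
    """Contiguous ``step``-Hz analysis bins; the last full bin below ``fmax``."""
    edges = np.arange(fmin, fmax + 1e-9, step)
    return [(float(a), float(a + step)) for a in edges if a + step <= fmax]


def tf_map(
    epochs: EpochSet,
    reference_window: tuple[float, float] = DEFAULT_REFERENCE,
    bands: list[tuple[float, float]] | None = None,
    smooth_s: float = 0.25,
    alpha: float = 0.05,
) -> ErdMap:
    """Time–frequency ERD/ERS map over 2-Hz bins (8–45 Hz by default)."""
    bands = bands if bands is not None else make_bands()
    values, masks = [], []
    for band in bands:
        curve = erd_timecourse(epochs, band, reference_window, smooth_s, alpha)
        values.append(curve.values)
        masks.append(curve.significant)
    return ErdMap(
        times=epochs.times,
        bands=bands,
        values=np.vstack(values),
        significant=np.vstack(masks),
        reference_window=tuple(reference_window),
        alpha=alpha,
    )


def cohens_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa from a 2×2 (or k×k) confusion matrix."""
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    po = np.trace(confusion) / total
    pe = (confusion.sum(axis=0) * confusion.sum(axis=1)).sum() / total**2
    if pe >= 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def candidate_bands(
    fmin: float = 8.0, fmax: float = 45.0, step: float = 2.0, max_bins: int = 4
) -> list[tuple[float, float]]:
    """All contiguous unions of 1–``max_bins`` adjacent bins within the range."""
    bins = make_bands(fmin, fmax, step)
    out = []
    for i in range(len(bins)):
        for w in range(1, max_bins + 1):
            if i + w <= len(bins):
                out.append((bins[i][0], bins[i + w - 1][1]))
    return out


def _loo_midpoint_kappa(log_ref: np.ndarray, log_reb: np.ndarray) -> float:
    """Leave-one-out midpoint-threshold classification kappa.

    Observations are per-trial log band powers; the classifier assigns an
    observation to 'rebound' when it exceeds the midpoint of the two class
    means fitted on the remaining observations.
    """
    obs = np.concatenate([log_ref, log_reb])
    lab = np.concatenate([np.zeros(len(log_ref), bool), np.ones(len(log_reb), bool)])
    sums = np.array([log_ref.sum(), log_reb.sum()])
    ns = np.array([len(log_ref), len(log_reb)])
    conf = np.zeros((2, 2))
    for x, is_reb in zip(obs, lab):
        k = int(is_reb)
        mean_own = (sums[k] - x) / (ns[k] - 1) if ns[k] > 1 else sums[k] / ns[k]
        mean_other = sums[1 - k] / ns[1 - k]
        means = (mean_own, mean_other) if k == 0 else (mean_other, mean_own)
        thr = 0.5 * (means[0] + means[1])
        pred = int(x > thr) if means[1] >= means[0] else int(x <= thr)
        conf[k, pred] += 1
    return cohens_kappa(conf)


def select_band(
    me_go_epochs: EpochSet,
    rebound_window: tuple[float, float] = (0.5, 2.5),
    reference_window: tuple[float, float] = DEFAULT_REFERENCE,
    candidates: list[tuple[float, float]] | None = None,
) -> BandSelection:
    """Subject-specific reactive band from the execution-block beta rebound.

    For each candidate band, per-trial log band power in the rebound window
    and in the reference window are classified (leave-one-out midpoint
    threshold); the band with the highest Cohen's kappa wins.  Ties prefer
    the wider band, then the lower low edge.
    """
    candidates = candidates if candidates is not None else candidate_bands()
    if not candidates:
        raise ParameterError("empty candidate band list")
    reb_mask = me_go_epochs.time_mask(rebound_window, half_open=False)
    ref_mask = me_go_epochs.time_mask(reference_window)
    scores: dict[tuple[float, float], float] = {}
    for band in candidates:
        trials = bandpass(me_go_epochs.data, band, me_go_epochs.sample_rate_hz)
        p = trials**2
        log_reb = np.log(p[:, reb_mask].mean(axis=1))
        log_ref = np.log(p[:, ref_mask].mean(axis=1))
        scores[band] = _loo_midpoint_kappa(log_ref, log_reb)
    best = max(scores, key=lambda b: (scores[b], b[1] - b[0], -b[0]))
    return BandSelection(
        band=best,
        kappa=scores[best],
        scores=scores,
        rebound_window=tuple(rebound_window),
        reference_window=tuple(reference_window),
    )


def extract_minimum(
    curve: "ErdCurve | np.ndarray",
    search_window: tuple[float, float] = (0.0, 1.0),
    times: np.ndarray | None = None,
) -> tuple[float, float]:
    """Latency (s) and amplitude (%) of the curve minimum in ``(a, b]``.

    The window is open at the left edge, closed at the right (the first
    second after cue onset by default); ties return the earliest sample.
    """
    if isinstance(curve, ErdCurve):
        values, t = curve.values, curve.times
    else:
        values, t = np.asarray(curve, dtype=float), np.asarray(times, dtype=float)
    a, b = search_window
    mask = (t > a + 1e-9) & (t <= b + 1e-9)
    if not mask.any():
        raise ParameterError(f"search window {search_window} outside the curve")
    vw = values[mask]
    tw = t[mask]
    i = int(np.argmin(vw))  # argmin returns the first occurrence on ties
    return float(tw[i]), float(vw[i])
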