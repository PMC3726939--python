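"""Independent brute-force transcriptions used as oracles in tests.

These deliberately use explicit Python loops and textbook formulas, sharing
no code path with the package implementation beyond the Butterworth filter
design itself.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.signal


def erd_inter_trial_variance(
    trials: np.ndarray,
    band: tuple[float, float],
    fs: float,
    times: np.ndarray,
    reference_window: tuple[float, float],
    smooth_s: float = 0.25,
) -> np.ndarray:
    """Literal transcription of the inter-trial variance ERD/ERS estimator."""
    sos = scipy.signal.butter(5, list(band), btype="bandpass", fs=fs, output="sos")
    n_trials, n_samples = trials.shape
    filt = np.empty_like(trials, dtype=float)
    for i in range(n_trials):
        filt[i] = scipy.signal.sosfiltfilt(sos, trials[i])
    # subtract the ensemble average sample by sample
    ens = np.empty(n_samples)
    for j in range(n_samples):
        ens[j] = sum(filt[i, j] for i in range(n_trials)) / n_trials
    power = np.empty(n_samples)
    for j in range(n_samples):
        power[j] = sum((filt[i, j] - ens[j]) ** 2 for i in range(n_trials)) / n_trials
    # centred moving average, partial windows at the edges
    # centring convention of a discrete length-w window: w//2 on the left for
    # even w (matches the implementation's 'same'-mode convolution)
    w = max(1, int(round(smooth_s * fs)))
    right = (w - 1) // 2
    left = w - 1 - right
    smoothed = np.empty(n_samples)
    for j in range(n_samples):
        lo = max(0, j - left)
        hi = min(n_samples, j + right + 1)
        smoothed[j] = sum(power[lo:hi]) / (hi - lo)
    a, b = reference_window
    ref = [smoothed[j] for j in range(n_samples) if a - 1e-9 <= times[j] < b - 1e-9]
    p_ref = sum(ref) / len(ref)
    return 100.0 * (smoothed - p_ref) / p_ref


def iqr_reject_transcription(deriv_abs: np.ndarray, factor: float = 1.5):
    """Literal transcription of the iterative class-wise IQR trial rejection.

    ``deriv_abs`` is (n_trials, n_values) of |first derivative| values.
    Returns (keep_mask, iteration_index_per_trial).
    """
    n = deriv_abs.shape[0]
    keep = [True] * n
    iteration = [math.nan] * n
    it = 0
    while True:
        it += 1
        pooled = np.concatenate([deriv_abs[i] for i in range(n) if keep[i]])
        q1 = np.percentile(pooled, 25)
        q3 = np.percentile(pooled, 75)
        iqd = q3 - q1
        lo = q1 - factor * iqd
        hi = q3 + factor * iqd
        newly = []
        for i in range(n):
            if keep[i] and any((v < lo) or (v > hi) for v in deriv_abs[i]):
                newly.append(i)
        if not newly:
            break
        for i in newly:
            keep[i] = False
            iteration[i] = it
        if not any(keep):
            break
    return np.asarray(keep, dtype=bool), np.asarray(iteration)


def paired_t_transcription(a: np.ndarray, b: np.ndarray):
    """Textbook paired t-test."""
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    import scipy.stats

    p = 2 * scipy.stats.t.sf(abs(t), n - 1)
    return t, p, n - 1


def pearson_transcription(x: np.ndarray, y: np.ndarray):
    """Textbook product-moment correlation with t-transform p-value."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    import scipy.stats

    p = 2 * scipy.stats.t.sf(abs(t), n - 2)
    return r, p
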