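"""Group-level inference for ERD and HR time courses.

Significance bands come from a t-percentile bootstrap: subjects are resampled
with replacement, the studentised statistic ``t* = (mean* − mean)/se*`` is
collected per time sample, and the band is formed from its empirical
quantiles.  A sample is called significant when zero lies outside the band.
The resampling unit is the subject (group curves); no correction across time
samples is applied — per-sample display convention, documented as a
reproduction choice rather than a statistical endorsement.

Feature-level inference uses the classical paired t-test (go vs. nogo
features) and Pearson product-moment correlation (ERD depth vs. HR
deceleration across subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .cardiac import HrResponse, extract_hr_minimum
from .erd import ErdCurve, extract_minimum
from .errors import InsufficientDataError, PairingError, ParameterError

DEFAULT_RESAMPLES = 500


@dataclass
class BootstrapBand:
    """Per-sample mean with lower/upper t-percentile bootstrap bounds."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    n_resamples: int
    significant: np.ndarray  # zero outside the band

    def __post_init__(self) -> None:
        if np.any(self.lower > self.mean + 1e-9) or np.any(self.upper < self.mean - 1e-9):
            raise ParameterError("bootstrap band must contain the mean")


def tpercentile_bootstrap(
    curves: np.ndarray,
    alpha: float = 0.05,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator = 0,
) -> BootstrapBand:
    """t-percentile bootstrap confidence band across subjects.

    ``curves`` is (n_subjects, n_samples).  Zero-variance samples yield a
    degenerate band equal to the mean.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    n, _ = curves.shape
    if n < 2:
        raise InsufficientDataError("bootstrap needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(n)

    idx = rng.integers(0, n, size=(n_resamples, n))
    res = curves[idx]  # (B, n, S)
    m_star = res.mean(axis=1)
    se_star = res.std(axis=1, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = (m_star - mean[None, :]) / se_star
    t_star[~np.isfinite(t_star)] = 0.0
    q_lo, q_hi = np.quantile(t_star, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    lower = mean - q_hi * se
    upper = mean - q_lo * se
    degenerate = se == 0
    lower[degenerate] = mean[degenerate]
    upper[degenerate] = mean[degenerate]
    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    # zero-within-band rule; a degenerate (zero-variance) sample is
    # significant exactly when its (exact) mean is nonzero
    significant = (lower > 0) | (upper < 0)
    significant[degenerate] = mean[degenerate] != 0
    return BootstrapBand(
        mean=mean,
        lower=lower,
        upper=upper,
        alpha=alpha,
        n_resamples=n_resamples,
        significant=significant,
    )


def compare_conditions(
    go_curves: np.ndarray,
    nogo_curves: np.ndarray,
    alpha: float = 0.05,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator = 0,
    times: np.ndarray | None = None,
) -> tuple[BootstrapBand, float | None]:
    """Per-sample significance of the paired go−nogo difference.

    Returns the bootstrap band of the per-subject differences and, when a
    time axis is supplied, the earliest post-cue significant time (or None).
    """
    go_curves = np.atleast_2d(np.asarray(go_curves, dtype=float))
    nogo_curves = np.atleast_2d(np.asarray(nogo_curves, dtype=float))
    if go_curves.shape != nogo_curves.shape:
        raise PairingError(
            f"paired comparison needs matching shapes, got {go_curves.shape} "
            f"vs {nogo_curves.shape}"
        )
    band = tpercentile_bootstrap(go_curves - nogo_curves, alpha, n_resamples, seed)
    earliest = None
    if times is not None:
        times = np.asarray(times)
        post = band.significant & (times > 1e-9)
        if post.any():
            earliest = float(times[np.argmax(post)])
    return band, earliest


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Two-sided paired t-test; returns ``(t, p, df)``.

    Zero-variance differences are degenerate: t is 0 (identical inputs) or
    signed infinity, flagged with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError("paired_t needs equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise InsufficientDataError("paired_t needs n >= 2")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0, df
        warnings.warn("zero-variance nonzero differences: infinite t", stacklevel=2)
        return float(np.sign(d.mean()) * np.inf), 0.0, df
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(p), df


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-transform p (df = n−2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError("pearson_r needs equal-length 1-D vectors")
    if x.size < 3:
        raise InsufficientDataError("pearson_r needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def build_feature_table(
    erd_curves: dict[object, dict[str, ErdCurve]],
    hr_responses: dict[object, dict[str, HrResponse]],
    conditions: tuple[str, str] = ("go", "nogo"),
    search_window: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Per-subject × condition features mirroring the group feature layout.

    Columns: ERD latency (ms) and amplitude (%), HR latency (ms) and
    amplitude (%); one row per subject and condition.  Use
    :func:`summarize_features` for the group mean ± SD.
    """
    rows = []
    for subj in erd_curves:
        for cond in conditions:
            if cond not in erd_curves[subj] or cond not in hr_responses.get(subj, {}):
                raise ParameterError(
                    f"subject {subj!r} missing condition {cond!r}"
                )
            el, ea = extract_minimum(erd_curves[subj][cond], search_window)
            hl, ha = extract_hr_minimum(hr_responses[subj][cond], search_window)
            rows.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "erd_latency_ms": 1000.0 * el,
                    "erd_amplitude_pct": ea,
                    "hr_latency_ms": 1000.0 * hl,
                    "hr_amplitude_pct": ha,
                }
            )
    return pd.DataFrame(rows)


def summarize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± SD per condition; SD is NaN (flagged) for one subject."""
    if table["subject"].nunique() == 1:
        warnings.warn("single subject: SD column undefined", stacklevel=2)
    return table.groupby("condition")[
        ["erd_latency_ms", "erd_amplitude_pct", "hr_latency_ms", "hr_amplitude_pct"]
    ].agg(["mean", "std"])
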