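"""Trial rejection: EMG thresholding and iterative IQR outlier removal.

Two bespoke rules with full per-trial provenance:

* **EMG rule** — a trial is rejected when any post-cue sample of the
  integrated EMG of either leg exceeds ``rest_mean + k · rest_SD``, with the
  rest statistics computed over that trial's own 5 s pre-cue window.  ``k=3``
  for nogo trials; ``k=5`` for go trials, because imagery can raise the tonus
  of the target muscles.
* **HR IQR rule** — per condition, the absolute first derivative of each
  trial's instantaneous HR is pooled over all surviving trials; any trial
  containing a value below ``Q1 − 1.5·IQD`` or above ``Q3 + 1.5·IQD`` is
  removed, and the procedure repeats on the survivors until an iteration
  removes nothing.  Whole-trial removal makes the procedure order-free and
  guarantees termination in at most ``n_trials`` iterations.

Trials removed by the EMG rule are never re-examined by the IQR rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AllTrialsRejectedError, InsufficientDataError, ParameterError
from .session import GO, NOGO, EpochSet

logger = logging.getLogger(__name__)

RULE_NONE = "none"
RULE_EMG_LEFT = "emg_left"
RULE_EMG_RIGHT = "emg_right"
RULE_HR_IQR = "hr_iqr"


@dataclass
class RejectionReport:
    """Per-trial keep/drop decisions with rule provenance.

    ``table`` has one row per trial: ``trial``, ``condition``, ``keep``,
    ``rule`` (none | emg_left | emg_right | hr_iqr) and ``iteration`` (IQR
    iteration index, NaN otherwise).  Quartiles use linear interpolation
    between order statistics (the common 'type 7' rule), recorded here for
    auditability.
    """

    table: pd.DataFrame
    quartile_rule: str = "linear (type 7)"

    @property
    def keep(self) -> np.ndarray:
        return self.table["keep"].to_numpy(dtype=bool)

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby("condition")["keep"]
            .agg(kept="sum", total="count")
            .assign(rejected=lambda d: d["total"] - d["kept"])
        )

    def merge(self, other: "RejectionReport") -> "RejectionReport":
        return RejectionReport(
            pd.concat([self.table, other.table], ignore_index=True),
            self.quartile_rule,
        )


def _make_table(n, condition, keep, rule, iteration) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "condition": condition,
            "keep": keep,
            "rule": rule,
            "iteration": iteration,
        }
    )


def emg_reject(
    emg_left: EpochSet,
    emg_right: EpochSet,
    condition: str,
    rest_window: tuple[float, float] = (-5.0, 0.0),
    k: float | None = None,
) -> tuple[np.ndarray, RejectionReport]:
    """Threshold rejection on the integrated EMG of both legs.

    ``k`` defaults to 3 for nogo and 5 for go.  Returns (keep mask, report).
    A zero-variance rest window degrades the threshold to the rest mean, with
    a warning.
    """
    if emg_left.data.shape != emg_right.data.shape:
        raise ParameterError("left/right EMG epoch shapes differ")
    if k is None:
        if condition not in (GO, NOGO):
            raise ParameterError(f"no default k for condition {condition!r}")
        k = 5.0 if condition == GO else 3.0
    rest_mask = emg_left.time_mask(rest_window)
    post_mask = emg_left.times >= -1e-9
    n = emg_left.n_trials
    keep = np.ones(n, dtype=bool)
    rules = np.array([RULE_NONE] * n, dtype=object)
    for leg_name, ep in ((RULE_EMG_LEFT, emg_left), (RULE_EMG_RIGHT, emg_right)):
        rest = ep.data[:, rest_mask]
        mu = rest.mean(axis=1)
        sd = rest.std(axis=1)
        if np.any(sd == 0):
            warnings.warn(
                "zero-variance EMG rest window: threshold degenerates to the mean",
                stacklevel=2,
            )
        thr = mu + k * sd
        fired = (ep.data[:, post_mask] > thr[:, None]).any(axis=1)
        newly = fired & keep
        keep[newly] = False
        rules[newly] = leg_name
    report = RejectionReport(
        _make_table(n, condition, keep, rules, np.full(n, np.nan))
    )
    logger.info("emg_reject(%s, k=%g): kept %d/%d", condition, k, keep.sum(), n)
    return keep, report


def hr_iqr_reject(
    hr_epochs: EpochSet,
    condition: str | None = None,
    iqr_factor: float = 1.5,
) -> tuple[np.ndarray, RejectionReport]:
    """Iterative class-wise IQR rejection on the |first derivative| of HR.

    Pools the per-sample absolute HR derivative over all surviving trials,
    computes Q1/Q3/IQD, removes every trial containing a value outside
    ``[Q1 − f·IQD, Q3 + f·IQD]``, and repeats until a fixed point.
    """
    n = hr_epochs.n_trials
    if n < 4:
        raise InsufficientDataError("IQR rejection needs at least 4 trials")
    condition = condition or hr_epochs.condition or "all"
    deriv = np.abs(np.diff(hr_epochs.data, axis=1))
    keep = np.ones(n, dtype=bool)
    rules = np.array([RULE_NONE] * n, dtype=object)
    iteration = np.full(n, np.nan)
    it = 0
    while True:
        it += 1
        pooled = deriv[keep].ravel()
        q1, q3 = np.percentile(pooled, [25, 75])  # linear interpolation (type 7)
        iqd = q3 - q1
        lo, hi = q1 - iqr_factor * iqd, q3 + iqr_factor * iqd
        out = ((deriv < lo) | (deriv > hi)).any(axis=1)
        newly = out & keep
        if not newly.any():
            break
        keep[newly] = False
        rules[newly] = RULE_HR_IQR
        iteration[newly] = it
        if not keep.any():
            raise AllTrialsRejectedError(
                f"IQR rejection removed every {condition} trial"
            )
    report = RejectionReport(_make_table(n, condition, keep, rules, iteration))
    logger.info(
        "hr_iqr_reject(%s): kept %d/%d after %d iteration(s)",
        condition, int(keep.sum()), n, it,
    )
    return keep, report
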