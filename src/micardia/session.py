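"""Session container, I/O and cue-locked epoching.

A :class:`Session` holds one subject's continuous multichannel recording
(15 EEG channels in microvolts, 2 integrated-EMG channels, 1 ECG channel in
millivolts, all on a common 250 Hz clock) together with the list of cue events
labelled ``go``/``nogo`` and the Laplacian montage.

Two on-disk representations are supported:

* the package's own plain-text columnar format (``.tsv`` with a JSON metadata
  header line) — lossless for events, high-precision for samples;
* EDF (European Data Format), one file per session plus a plain-text event
  table.  Reading uses :mod:`mne` when available; writing uses the minimal
  16-bit writer in this module, so round-trips preserve samples to 16-bit
  quantisation.

Epoching cuts cue-locked trials on a window given in seconds relative to cue
onset (default [−5, +6] s, wide enough to contain the 2–4 s pre-cue reference
interval and the post-cue dynamics through the beta rebound and the heart-rate
acceleration).  The sample at time 0 is the cue-onset sample; trials that
would extend past either recording edge are dropped and counted.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ChannelMissingError,
    EmptyEpochsError,
    FormatError,
    MontageError,
    ParameterError,
)
from .montage import DEFAULT_MONTAGE, ECG_CHANNEL, EEG_CHANNELS, EMG_CHANNELS

logger = logging.getLogger(__name__)

GO = "go"
NOGO = "nogo"

#: default epoch window in seconds relative to cue onset
DEFAULT_WINDOW = (-5.0, 6.0)


@dataclass
class Session:
    """One subject's continuous recording plus labelled cue events."""

    eeg: np.ndarray  # (n_eeg_channels, n_samples), microvolts
    emg: np.ndarray  # (2, n_samples), integrated-EMG units
    ecg: np.ndarray  # (n_samples,), millivolts
    sample_rate_hz: float
    events: pd.DataFrame  # columns: onset_sample (int), label (str)
    eeg_channels: list[str] = field(default_factory=lambda: list(EEG_CHANNELS))
    montage: dict[str, tuple[str, tuple[str, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_MONTAGE)
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        n = self.eeg.shape[1]
        if self.emg.shape != (2, n) or self.ecg.shape != (n,):
            raise FormatError(
                "all signals must share one length/rate: "
                f"eeg {self.eeg.shape}, emg {self.emg.shape}, ecg {self.ecg.shape}"
            )
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")
        if len(self.eeg_channels) != self.eeg.shape[0]:
            raise FormatError("eeg_channels length does not match eeg rows")
        if not isinstance(self.events, pd.DataFrame):
            self.events = pd.DataFrame(
                list(self.events), columns=["onset_sample", "label"]
            )
        onsets = self.events["onset_sample"].to_numpy()
        if len(onsets) and (onsets.min() < 0 or onsets.max() >= n):
            raise FormatError("event onsets fall outside the recording")
        for name, (centre, neighbours) in self.montage.items():
            for ch in (centre, *neighbours):
                if ch not in self.eeg_channels:
                    raise MontageError(
                        f"montage {name!r} references missing channel {ch!r}"
                    )

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        """Return one EEG channel by name."""
        try:
            return self.eeg[self.eeg_channels.index(name)]
        except ValueError:
            raise ChannelMissingError(f"no EEG channel named {name!r}") from None


@dataclass
class EpochSet:
    """Cue-locked trial matrix for one signal/condition.

    ``data`` has one row per trial; ``times`` is seconds relative to cue
    onset, with time 0 exactly on the cue-onset sample.
    """

    data: np.ndarray  # (n_trials, n_times)
    times: np.ndarray  # (n_times,)
    sample_rate_hz: float
    condition: str | None = None
    derivation: str | None = None
    n_dropped: int = 0
    event_index: np.ndarray | None = None  # indices into the session event list

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape[1] != self.times.size:
            raise ParameterError("data and time axis lengths differ")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_mask(self, window: tuple[float, float], half_open: bool = True) -> np.ndarray:
        """Boolean mask for times in ``[a, b)`` (or ``[a, b]``)."""
        a, b = window
        if half_open:
            return (self.times >= a - 1e-9) & (self.times < b - 1e-9)
        return (self.times >= a - 1e-9) & (self.times <= b + 1e-9)

    def subset(self, keep: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to the trials selected by ``keep``."""
        return EpochSet(
            data=self.data[keep],
            times=self.times,
            sample_rate_hz=self.sample_rate_hz,
            condition=self.condition,
            derivation=self.derivation,
            n_dropped=self.n_dropped,
            event_index=None if self.event_index is None else self.event_index[keep],
        )


def laplacian(session: Session, derivation: str) -> np.ndarray:
    """Small-Laplacian virtual channel: centre minus mean of its neighbours.

    Linear, and removes any signal common to the centre and all neighbours,
    which is what sharpens the spatial focus over the targeted cortex patch.
    """
    if derivation not in session.montage:
        raise MontageError(f"unknown derivation {derivation!r}")
    centre, neighbours = session.montage[derivation]
    if len(neighbours) < 1:
        raise MontageError(f"derivation {derivation!r} has no neighbours")
    centre_sig = session.channel(centre)
    neigh = np.stack([session.channel(ch) for ch in neighbours])
    return centre_sig - neigh.mean(axis=0)


def epoch(
    signal: np.ndarray,
    events: pd.DataFrame,
    sample_rate_hz: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
    condition: str | None = None,
    derivation: str | None = None,
) -> EpochSet:
    """Cut cue-locked epochs from a 1-D signal.

    Parameters
    ----------
    signal
        Continuous 1-D signal on the session clock.
    events
        DataFrame with ``onset_sample`` and ``label`` columns.
    window
        ``(t_min, t_max)`` in seconds relative to cue onset.
    condition
        If given, keep only events with this label.

    Trials that would run past either end of the recording are excluded and
    counted in ``n_dropped`` (and logged).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ParameterError("epoch() expects a 1-D signal")
    if window[0] >= window[1]:
        raise ParameterError("epoch window must satisfy t_min < t_max")
    fs = float(sample_rate_hz)
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    offsets = np.arange(i0, i1 + 1)
    times = offsets / fs

    sel = events
    if condition is not None:
        sel = events[events["label"] == condition]
    onsets = sel["onset_sample"].to_numpy(dtype=int)
    idx = sel.index.to_numpy()

    ok = (onsets + i0 >= 0) & (onsets + i1 < signal.size)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "epoch: dropped %d/%d trials extending past the recording edge",
            n_dropped,
            onsets.size,
        )
    onsets = onsets[ok]
    if onsets.size == 0:
        raise EmptyEpochsError(
            f"no complete epochs for condition {condition!r} in window {window}"
        )
    data = signal[onsets[:, None] + offsets[None, :]]
    return EpochSet(
        data=data,
        times=times,
        sample_rate_hz=fs,
        condition=condition,
        derivation=derivation,
        n_dropped=n_dropped,
        event_index=idx[ok],
    )


# ---------------------------------------------------------------------------
# columnar plain-text format
# ---------------------------------------------------------------------------

_MAGIC = "# micardia-session v1"


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to the single-file columnar text format.

    Line 1 is a magic marker, line 2 a JSON header (rate, channel names,
    montage, events, free-form meta), then a tab-separated sample matrix with
    one column per channel.
    """
    path = Path(path)
    header = {
        "sample_rate_hz": session.sample_rate_hz,
        "eeg_channels": session.eeg_channels,
        "montage": {k: [c, list(n)] for k, (c, n) in session.montage.items()},
        "events": [
            [int(r.onset_sample), str(r.label)] for r in session.events.itertuples()
        ],
        "meta": session.meta,
    }
    cols = session.eeg_channels + EMG_CHANNELS + [ECG_CHANNEL]
    mat = np.vstack([session.eeg, session.emg, session.ecg[None, :]]).T
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write("# " + json.dumps(header) + "\n")
        df = pd.DataFrame(mat, columns=cols)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_session(path: str | Path) -> Session:
    """Read a session from the columnar format (or EDF, by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_session_edf(path)
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _MAGIC:
            raise FormatError(f"{path} is not a micardia session file")
        header_line = fh.readline()
        if not header_line.startswith("# "):
            raise FormatError(f"{path}: missing JSON header line")
        header = json.loads(header_line[2:])
        df = pd.read_csv(fh, sep="\t")
    eeg_channels = header["eeg_channels"]
    for ch in eeg_channels + EMG_CHANNELS + [ECG_CHANNEL]:
        if ch not in df.columns:
            raise ChannelMissingError(f"{path}: channel {ch!r} missing")
    events = pd.DataFrame(header["events"], columns=["onset_sample", "label"])
    return Session(
        eeg=df[eeg_channels].to_numpy().T,
        emg=df[EMG_CHANNELS].to_numpy().T,
        ecg=df[ECG_CHANNEL].to_numpy(),
        sample_rate_hz=float(header["sample_rate_hz"]),
        events=events,
        eeg_channels=list(eeg_channels),
        montage={k: (v[0], tuple(v[1])) for k, v in header["montage"].items()},
        meta=header.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_session_edf(session: Session, path: str | Path) -> Path:
    """Write a session as EDF plus a sidecar event table ``<stem>.events.tsv``.

    Samples are stored as 16-bit integers scaled channel-wise to the physical
    range, the usual EDF quantisation.  Record duration is 1 s; a trailing
    partial second is zero-padded (the padded length is recoverable from the
    event table's ``n_samples`` header and is irrelevant for epoching because
    no events sit in the pad).
    """
    path = Path(path)
    fs = session.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF export requires an integer sample rate")
    spr = int(round(fs))  # samples per 1 s record

    labels = session.eeg_channels + EMG_CHANNELS + [ECG_CHANNEL]
    units = ["uV"] * len(session.eeg_channels) + ["au", "au", "mV"]
    signals = np.vstack([session.eeg, session.emg, session.ecg[None, :]])
    n_sig, n_samp = signals.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, :n_samp] = signals

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    buf = io.BytesIO()
    buf.write(_edf_ascii("0", 8))
    buf.write(_edf_ascii("X X X X", 80))  # anonymous patient
    buf.write(_edf_ascii("Startdate X X X X", 80))
    buf.write(_edf_ascii("01.01.00", 8))
    buf.write(_edf_ascii("00.00.00", 8))
    buf.write(_edf_ascii(256 + 256 * n_sig, 8))
    buf.write(_edf_ascii("", 44))
    buf.write(_edf_ascii(n_rec, 8))
    buf.write(_edf_ascii(1, 8))  # record duration, seconds
    buf.write(_edf_ascii(n_sig, 4))
    for lab in labels:
        buf.write(_edf_ascii(lab, 16))
    for _ in labels:
        buf.write(_edf_ascii("", 80))  # transducer
    for u in units:
        buf.write(_edf_ascii(u, 8))
    for v in phys_min:
        buf.write(_edf_ascii(f"{v:.8g}"[:8], 8))
    for v in phys_max:
        buf.write(_edf_ascii(f"{v:.8g}"[:8], 8))
    for _ in labels:
        buf.write(_edf_ascii(dig_min, 8))
    for _ in labels:
        buf.write(_edf_ascii(dig_max, 8))
    for _ in labels:
        buf.write(_edf_ascii("", 80))  # prefiltering
    for _ in labels:
        buf.write(_edf_ascii(spr, 8))
    for _ in labels:
        buf.write(_edf_ascii("", 32))  # reserved

    for r in range(n_rec):
        chunk = digital[:, r * spr : (r + 1) * spr]
        buf.write(chunk.tobytes())  # channel-major within record, little-endian i2

    path.write_bytes(buf.getvalue())

    ev_path = path.with_suffix(".events.tsv")
    with open(ev_path, "w") as fh:
        fh.write(f"# sample_rate_hz={session.sample_rate_hz}\tn_samples={n_samp}\n")
        session.events.to_csv(fh, sep="\t", index=False)
    return path


def _read_edf_raw(path: Path) -> tuple[list[str], np.ndarray, float]:
    """Minimal EDF reader used when :mod:`mne` is unavailable."""
    data = path.read_bytes()
    n_sig = int(data[252:256].decode("ascii").strip())
    n_rec = int(data[236:244].decode("ascii").strip())
    rec_dur = float(data[244:252].decode("ascii").strip())
    off = 256
    labels = [
        data[off + 16 * i : off + 16 * (i + 1)].decode("ascii").strip()
        for i in range(n_sig)
    ]
    off += 16 * n_sig + 80 * n_sig + 8 * n_sig

    def _floats(o):
        return [float(data[o + 8 * i : o + 8 * (i + 1)].decode("ascii")) for i in range(n_sig)]

    phys_min = _floats(off)
    phys_max = _floats(off + 8 * n_sig)
    dig_min = _floats(off + 16 * n_sig)
    dig_max = _floats(off + 24 * n_sig)
    off += 32 * n_sig + 80 * n_sig
    spr = [int(data[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip()) for i in range(n_sig)]
    header_len = int(data[184:192].decode("ascii").strip())

    raw = np.frombuffer(data, dtype="<i2", offset=header_len)
    per_rec = sum(spr)
    raw = raw[: n_rec * per_rec].reshape(n_rec, per_rec)
    out = []
    pos = 0
    for i in range(n_sig):
        dig = raw[:, pos : pos + spr[i]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        out.append((dig - dig_min[i]) * gain + phys_min[i])
        pos += spr[i]
    fs = spr[0] / rec_dur
    return labels, np.vstack(out), fs


def read_session_edf(path: str | Path) -> Session:
    """Read an EDF session plus its sidecar event table ``<stem>.events.tsv``.

    The EDF payload is decoded in physical units (channel-wise 16-bit
    digital→physical scaling); the package's tests cross-check the decoding
    against :mod:`mne`'s EDF reader.
    """
    path = Path(path)
    labels, mat, fs = _read_edf_raw(path)

    ev_path = path.with_suffix(".events.tsv")
    n_samples = None
    events = pd.DataFrame(columns=["onset_sample", "label"])
    if ev_path.exists():
        with open(ev_path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "n_samples":
                        n_samples = int(v)
            else:
                fh.seek(0)
            events = pd.read_csv(fh, sep="\t")
    if n_samples is not None:
        mat = mat[:, :n_samples]

    for ch in EMG_CHANNELS + [ECG_CHANNEL]:
        if ch not in labels:
            raise ChannelMissingError(f"{path}: channel {ch!r} missing from EDF")
    eeg_channels = [c for c in labels if c not in EMG_CHANNELS + [ECG_CHANNEL]]
    by = {c: mat[i] for i, c in enumerate(labels)}
    montage = {
        k: v
        for k, v in DEFAULT_MONTAGE.items()
        if all(ch in labels for ch in (v[0], *v[1]))
    }
    return Session(
        eeg=np.stack([by[c] for c in eeg_channels]),
        emg=np.stack([by[c] for c in EMG_CHANNELS]),
        ecg=by[ECG_CHANNEL],
        sample_rate_hz=fs,
        events=events,
        eeg_channels=eeg_channels,
        montage=montage,
    )
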