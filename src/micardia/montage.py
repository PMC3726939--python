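"""Electrode montage for the three small-Laplacian derivations.

Fifteen electrodes arranged as three crosses of five (centre plus four
orthogonal neighbours at 2.5 cm) over C3, Cz and C4 — the left-hand, foot and
right-hand sensorimotor areas.  A Laplacian derivation is the centre electrode
minus the mean of its neighbours.
"""

from __future__ import annotations

#: derivation name -> (centre channel, neighbour channels)
DEFAULT_MONTAGE: dict[str, tuple[str, tuple[str, ...]]] = {
    centre: (centre, (f"{centre}-a", f"{centre}-p", f"{centre}-l", f"{centre}-r"))
    for centre in ("C3", "Cz", "C4")
}

#: the 15 EEG channel names in recording order (centre first per group)
EEG_CHANNELS: list[str] = [
    name
    for centre, neighbours in DEFAULT_MONTAGE.values()
    for name in (centre, *neighbours)
]

EMG_CHANNELS: list[str] = ["EMG-left", "EMG-right"]
ECG_CHANNEL: str = "ECG"

#: the foot-representation (vertex) derivation analysed by default
FOOT_DERIVATION = "Cz"
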