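"""Electrode montages: channel names, schematic 3-D positions, mirror pairs.

Positions are built from a schematic 10-10 grid (row = front-to-back line,
column = lateral index) projected onto the unit sphere. They are intended
for neighbor lookup, laterality and interpolation weights, not for source
modelling: only ordinal distance relations matter downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "make_montage", "ADULT_CHANNELS", "INFANT_CHANNELS"]

# Front-to-back 10-10 line order used for schematic coordinates.
_ROWS = ["Fp", "AF", "F", "FC", "C", "CP", "P", "PO", "O", "I"]
_ROW_OF_PREFIX = {
    "Fp": 0, "AF": 1, "F": 2, "FT": 3, "FC": 3, "T": 4, "C": 4,
    "TP": 5, "CP": 5, "P": 6, "PO": 7, "O": 8, "I": 9,
}
# Lateral slot for each 10-10 numeric suffix (negative = left).
_COL_OF_NUM = {1: -1, 2: 1, 3: -2, 4: 2, 5: -3, 6: 3, 7: -4, 8: 4, 9: -5, 10: 5}

_NAME_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")

# 55 recording channels, 10-10 subset (ground AFz and reference Cz omitted).
ADULT_CHANNELS = [
    "Fp1", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F3", "F1", "Fz", "F2", "F4", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C3", "C1", "C2", "C4", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P3", "P1", "Pz", "P2", "P4", "P8", "P10",
    "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2",
]

# 32 recording channels; the posterior 17 match the infant ROI channels.
INFANT_CHANNELS = [
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "C4", "T8",
    "CP5", "CP6",
    "P9", "P7", "P3", "Pz", "P4", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]


def _parse(name: str) -> tuple[int, float]:
    """Return (row, lateral column) for a 10-10 channel name."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unrecognized channel name: {name!r}")
    prefix, suffix = m.group(1), m.group(2)
    # T7/T8 and TP/FT sit on the C/CP/FC lines at the outermost slots.
    if prefix in ("T", "TP", "FT"):
        row = _ROW_OF_PREFIX[prefix]
        num = int(suffix)
        col = -4 if num in (7, 9) else 4
        return row, float(col)
    row = _ROW_OF_PREFIX[prefix]
    if suffix == "z":
        return row, 0.0
    return row, float(_COL_OF_NUM[int(suffix)])


def _position(name: str) -> np.ndarray:
    row, col = _parse(name)
    u = (row - 4) / 4.5        # front (-) to back (+)
    v = col / 5.0              # left (-) to right (+)
    r = np.hypot(u, v)
    theta = r * (np.pi / 2) * 1.05   # 9/10-suffixed channels dip below the equator
    if r == 0:
        return np.array([0.0, 0.0, 1.0])
    x = np.sin(theta) * (v / r)
    y = -np.sin(theta) * (u / r)
    z = np.cos(theta)
    return np.array([x, y, z])


def _mirror_name(name: str) -> str | None:
    m = _NAME_RE.match(name)
    if m is None or m.group(2) == "z":
        return None
    prefix, num = m.group(1), int(m.group(2))
    partner = num + 1 if num % 2 == 1 else num - 1
    return f"{prefix}{partner}"


@dataclass
class Montage:
    """Channel names with schematic positions and left/right mirror pairs."""

    channel_names: list[str]
    positions: np.ndarray  # (n_channels, 3), unit sphere
    mirror_pairs: list[tuple[str, str]] = field(default_factory=list)
    midline: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for a, b in self.mirror_pairs:
            if a == b:
                raise ValueError(f"mirror pair maps {a} to itself")
        for ch in self.midline:
            if any(ch in pair for pair in self.mirror_pairs):
                raise ValueError(f"midline channel {ch} has a mirror partner")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def indices(self, names: list[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names])

    def mirror_of(self, name: str) -> str | None:
        for a, b in self.mirror_pairs:
            if a == name:
                return b
            if b == name:
                return a
        return None

    def symmetric_set(self) -> list[str]:
        """Channels forming the symmetric-average reference: all paired
        channels plus the midline."""
        out = []
        for a, b in self.mirror_pairs:
            out.extend([a, b])
        out.extend(self.midline)
        return [ch for ch in self.channel_names if ch in set(out)]

    def frontal_central(self) -> list[str]:
        """Channels on the Fp/AF/F/FC/C lines (blink-sensitive sites)."""
        keep = []
        for ch in self.channel_names:
            row, _ = _parse(ch)
            if row <= 4:
                keep.append(ch)
        return keep

    def laterality(self, name: str) -> int:
        """-1 left, 0 midline, +1 right, by schematic x position."""
        x = self.positions[self.index(name), 0]
        if abs(x) < 1e-9:
            return 0
        return int(np.sign(x))


def make_montage(preset: str) -> Montage:
    """Build a montage preset: ``"adult"`` (55 ch) or ``"infant"`` (32 ch)."""
    if preset == "adult":
        names = list(ADULT_CHANNELS)
    elif preset == "infant":
        names = list(INFANT_CHANNELS)
    else:
        raise ValueError(f"unknown montage preset: {preset!r}")
    positions = np.array([_position(n) for n in names])
    pairs = []
    seen = set()
    midline = []
    for n in names:
        partner = _mirror_name(n)
        if partner is None:
            midline.append(n)
        elif partner in names and n not in seen:
            pairs.append((n, partner) if n < partner else (partner, n))
            seen.update({n, partner})
    # de-duplicate pairs while keeping montage order
    uniq = []
    for p in pairs:
        if p not in uniq:
            uniq.append(p)
    return Montage(names, positions, uniq, midline)
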