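"""Epoch screening, ROI construction and significance summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AmplitudeSpectrum
from .montage import Montage
from .spectral import INFANT_RECIPE, NoiseRecipe, SummedResponse, zscore_at

__all__ = [
    "ROIDefinition",
    "ScreeningDecision",
    "SignificanceSummary",
    "ROI_PRESETS",
    "screen_epoch",
    "define_rois",
    "roi_response",
    "significance_summary",
]


@dataclass
class ROIDefinition:
    """A named electrode cluster."""

    name: str
    channels: list[str]
    construction: str = "preset"  # preset | ranked | fraction

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ROI must contain at least one channel")


#: The study's fixed ROI channel lists.
ROI_PRESETS: dict[str, list[ROIDefinition]] = {
    "adult_face": [
        ROIDefinition("rOT", ["P8", "PO8", "P10", "PO10"]),
        ROIDefinition("lOT", ["P7", "PO7", "P9", "PO9"]),
        ROIDefinition("mO", ["PO3", "PO4", "O1", "Oz", "O2"]),
    ],
    "adult_general": [
        ROIDefinition("mO", ["PO4", "PO3", "PO8", "O1", "Oz", "O2"]),
    ],
    "infant_face": [
        ROIDefinition("rOT", ["CP6", "P4", "P8", "PO8", "P10"]),
        ROIDefinition("lOT", ["CP5", "P3", "P7", "PO7", "P9"]),
        ROIDefinition("mO", ["O1", "O2", "PO3", "PO4", "Oz", "POz", "Pz"]),
    ],
    "infant_general": [
        ROIDefinition("mO", ["POz", "O1", "Oz", "O2"]),
    ],
}


@dataclass
class ScreeningDecision:
    keep: bool
    max_z: float
    best_channel: str
    best_freq_hz: float
    z_table: dict[tuple[str, float], float] = field(default_factory=dict)


@dataclass
class SignificanceSummary:
    """Group and individual significance of a response."""

    z_threshold: float
    group_z_by_channel: dict[str, float]
    group_z_by_roi: dict[str, float]
    significant_channels: list[str]
    counts_per_participant: np.ndarray  # channels with Z > threshold
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


def screen_epoch(
    epoch_spectrum: AmplitudeSpectrum,
    channels: tuple[str, ...] = ("POz", "O1", "Oz", "O2"),
    freqs_hz: tuple[float, ...] = (6.0, 12.0),
    z_threshold: float = 2.32,
    recipe: NoiseRecipe = INFANT_RECIPE,
) -> ScreeningDecision:
    """Keep an epoch iff any (channel, frequency) Z exceeds ``z_threshold``.

    Z is computed with the infant noise recipe on the single-epoch raw
    spectrum (no condition averaging).
    """
    missing = [c for c in channels if c not in epoch_spectrum.channel_names]
    if missing:
        raise ValueError(f"screening channels missing from spectrum: {missing}")
    idx = [epoch_spectrum.channel_names.index(c) for c in channels]
    table: dict[tuple[str, float], float] = {}
    for f in freqs_hz:
        z_all = zscore_at(epoch_spectrum, f, recipe)
        for c, i in zip(channels, idx):
            table[(c, f)] = float(z_all[i])
    best = max(table, key=lambda k: table[k])
    max_z = table[best]
    return ScreeningDecision(
        keep=bool(max_z > z_threshold),
        max_z=float(max_z),
        best_channel=best[0],
        best_freq_hz=best[1],
        z_table=table,
    )


def define_rois(
    group_summed_response: SummedResponse,
    montage: Montage,
    mode: str = "preset",
    k_or_fraction: float | None = None,
    preset: str | None = None,
) -> list[ROIDefinition]:
    """Build ROIs from the group-mean summed response.

    ``mode="preset"`` returns the fixed study lists (see ``ROI_PRESETS``).
    ``mode="ranked"`` takes the top-k channels by summed corrected
    amplitude, adds each one's mirror partner, and partitions the result
    into left/right/midline clusters by schematic x position. Ties break
    alphabetically so the construction is deterministic.
    ``mode="fraction"`` returns the top ``ceil(fraction * n_channels)``
    channels as a single ROI.
    """
    if mode == "preset":
        if preset not in ROI_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(ROI_PRESETS)}"
            )
        return [ROIDefinition(r.name, list(r.channels), "preset")
                for r in ROI_PRESETS[preset]]

    resp = group_summed_response
    order = sorted(
        range(len(resp.channel_names)),
        key=lambda i: (-resp.amplitude_uv[i], resp.channel_names[i]),
    )
    if mode == "fraction":
        if k_or_fraction is None or not 0 < k_or_fraction <= 1:
            raise ValueError("fraction mode needs k_or_fraction in (0, 1]")
        k = int(np.ceil(k_or_fraction * len(resp.channel_names)))
        chans = sorted(resp.channel_names[i] for i in order[:k])
        return [ROIDefinition("mO", chans, "fraction")]
    if mode != "ranked":
        raise ValueError(f"unknown ROI mode {mode!r}")

    if k_or_fraction is None:
        raise ValueError("ranked mode needs k_or_fraction (number of seeds)")
    k = int(k_or_fraction)
    selected: set[str] = set()
    for i in order[:k]:
        name = resp.channel_names[i]
        selected.add(name)
        partner = montage.mirror_of(name)
        if partner is not None and partner in resp.channel_names:
            selected.add(partner)
    left = sorted(c for c in selected if montage.laterality(c) < 0)
    right = sorted(c for c in selected if montage.laterality(c) > 0)
    mid = sorted(c for c in selected if montage.laterality(c) == 0)
    rois = []
    if right:
        rois.append(ROIDefinition("rOT", right, "ranked"))
    if left:
        rois.append(ROIDefinition("lOT", left, "ranked"))
    if mid:
        rois.append(ROIDefinition("mO", mid, "ranked"))
    return rois


def roi_response(
    summed_response: SummedResponse,
    roi: ROIDefinition,
    recipe: NoiseRecipe | None = None,
) -> tuple[float, float]:
    """Mean summed corrected amplitude over the ROI channels, and the Z
    recomputed on the ROI-averaged summed chunk (falls back to the mean of
    channel Zs when the chunk is unavailable)."""
    missing = [c for c in roi.channels if c not in summed_response.channel_names]
    if missing:
        raise ValueError(f"ROI channels missing: {missing}")
    idx = [summed_response.channel_names.index(c) for c in roi.channels]
    amp = float(summed_response.amplitude_uv[idx].mean())

    if summed_response.summed_chunk is not None and recipe is not None:
        from .core import AmplitudeSpectrum as _AS
        from .spectral import noise_stats

        chunk = summed_response.summed_chunk[idx].mean(axis=0, keepdims=True)
        w = recipe.side_bins
        spec = _AS(chunk, 1.0, 1.0, ["roi"], kind="raw")
        mean, sd, flag = noise_stats(spec, w, recipe)
        diff = chunk[0, w] - mean[0]
        z = np.inf * np.sign(diff) if flag[0] else diff / sd[0]
        return amp, float(z)
    z = float(summed_response.z[idx].mean())
    return amp, z


def significance_summary(
    individual_z: np.ndarray,
    group_z: np.ndarray,
    channel_names: list[str],
    rois: list[ROIDefinition] | None = None,
    z_threshold: float = 1.64,
) -> SignificanceSummary:
    """Summarize group and per-participant significance.

    ``individual_z`` is (n_participants, n_channels); ``group_z`` is
    (n_channels,). Per participant, the count of channels with Z >
    threshold is reported; ROI-level group Z is the mean over ROI channels.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    individual_z = np.atleast_2d(np.asarray(individual_z, dtype=float))
    group_z = np.asarray(group_z, dtype=float)
    if individual_z.shape[1] != len(channel_names) or \
            group_z.shape[0] != len(channel_names):
        raise ValueError("Z maps and channel names must share channels")

    by_channel = {c: float(z) for c, z in zip(channel_names, group_z)}
    by_roi = {}
    for roi in rois or []:
        idx = [channel_names.index(c) for c in roi.channels]
        by_roi[roi.name] = float(group_z[idx].mean())
    sig = [c for c, z in by_channel.items() if z > z_threshold]
    counts = (individual_z > z_threshold).sum(axis=1)
    return SignificanceSummary(
        z_threshold=z_threshold,
        group_z_by_channel=by_channel,
        group_z_by_roi=by_roi,
        significant_channels=sig,
        counts_per_participant=counts,
        channel_names=list(channel_names),
    )
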