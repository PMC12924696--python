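"""Spectral quantification of frequency-tagged responses.

Exact-cycle epoching, condition averaging, single-sided FFT amplitude
spectra, neighbor-bin noise estimation (adult and infant recipes),
baseline-corrected amplitudes, spectral Z-scores, harmonic selection and
chunk summation.

Amplitude normalization is 2|X_k|/N for k > 0 and |X_0|/N for DC, so a
unit-amplitude cosine landing on an exact bin reads 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AmplitudeSpectrum, Epoch, Segment

__all__ = [
    "NoiseRecipe",
    "ADULT_RECIPE",
    "INFANT_RECIPE",
    "HarmonicSet",
    "SummedResponse",
    "epoch_exact_cycles",
    "average_epochs_by_condition",
    "amplitude_spectrum",
    "noise_stats",
    "correct_and_zscore",
    "select_harmonics",
    "sum_harmonic_chunks",
]

Z_INF = np.inf  # sentinel reported when the noise SD is exactly 0


@dataclass(frozen=True)
class NoiseRecipe:
    """How to estimate the noise floor around a target bin.

    ``side_bins`` neighbors are collected on each side; the innermost
    ``exclude_adjacent`` bins per side are dropped; optionally the global
    max and min of the remainder are dropped. The infant variant first
    removes a linear trend fit on the ``detrend_range`` offsets (per side)
    and then computes mean/SD from the ``z_range`` offsets.

    Ranges are inclusive offsets in bins from the target.
    """

    side_bins: int = 12
    exclude_adjacent: int = 1
    exclude_extremes: bool = True
    detrend_range: tuple[int, int] | None = None
    z_range: tuple[int, int] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.side_bins < 2:
            raise ValueError("side_bins must be >= 2")
        for rng in (self.detrend_range, self.z_range):
            if rng is not None:
                lo, hi = rng
                if not (0 < lo <= hi <= self.side_bins):
                    raise ValueError(f"range {rng} outside side_bins")


#: Adult recipe: 12 bins per side, drop the adjacent bin on each side and the
#: global max/min of the remainder -> 20 noise bins.
ADULT_RECIPE = NoiseRecipe(side_bins=12, exclude_adjacent=1,
                           exclude_extremes=True, name="adult")

#: Infant recipe: 16 bins per side minus adjacent -> 30 neighbors; offsets
#: 2-6 per side fit the linear detrend; offsets 6-16 per side (max/min
#: dropped) provide the Z mean/SD.
INFANT_RECIPE = NoiseRecipe(side_bins=16, exclude_adjacent=1,
                            exclude_extremes=True,
                            detrend_range=(2, 6), z_range=(6, 16),
                            name="infant")


@dataclass
class HarmonicSet:
    """Harmonics retained for one response."""

    fundamental_hz: float
    retained_indices: list[int]
    excluded_overlaps: list[int] = field(default_factory=list)
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        self.retained_indices = sorted(self.retained_indices)
        if any(k <= 0 for k in self.retained_indices):
            raise ValueError("harmonic indices must be positive")
        if set(self.retained_indices) & set(self.excluded_overlaps):
            raise ValueError("retained and excluded harmonics overlap")

    @property
    def frequencies_hz(self) -> list[float]:
        return [k * self.fundamental_hz for k in self.retained_indices]

    @property
    def n_retained(self) -> int:
        return len(self.retained_indices)

    @property
    def highest_harmonic(self) -> int:
        """Highest harmonic number reached, counting skipped overlaps."""
        if not self.retained_indices:
            return 0
        return max(self.retained_indices + list(self.excluded_overlaps))


@dataclass
class SummedResponse:
    """Per-channel summed baseline-corrected amplitude and summed-chunk Z."""

    amplitude_uv: np.ndarray      # (n_channels,)
    z: np.ndarray                 # (n_channels,)
    channel_names: list[str]
    harmonic_set: HarmonicSet
    condition_label: str = ""
    summed_chunk: np.ndarray | None = None  # (n_channels, chunk width)

    def channel(self, name: str) -> tuple[float, float]:
        i = self.channel_names.index(name)
        return float(self.amplitude_uv[i]), float(self.z[i])


def epoch_exact_cycles(
    segment: Segment,
    start_offset_s: float = 0.833,
    duration_s: float = 34.0,
    oddball_hz: float = 1.0,
) -> Epoch:
    """Cut an epoch spanning an exact integer number of oddball cycles.

    Offsets snap to the nearest sample; the epoch length in samples is
    exactly ``round(duration_s * rate_hz)``.
    """
    n_cycles = duration_s * oddball_hz
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ValueError(
            f"duration {duration_s} s is not an integer number of "
            f"{oddball_hz}-Hz oddball cycles"
        )
    i0 = int(round(start_offset_s * segment.rate_hz))
    n = int(round(duration_s * segment.rate_hz))
    if i0 + n > segment.n_samples:
        raise ValueError("segment does not cover offset + duration")
    return Epoch(
        segment.data[:, i0:i0 + n].copy(),
        segment.rate_hz,
        list(segment.channel_names),
        duration_s=duration_s,
        condition_label=segment.condition_label,
    )


def average_epochs_by_condition(epochs: list[Epoch]) -> dict[str, Epoch]:
    """Element-wise time-domain mean of epochs sharing a condition label."""
    if not epochs:
        raise ValueError("no epochs to average")
    by_cond: dict[str, list[Epoch]] = {}
    for ep in epochs:
        by_cond.setdefault(ep.condition_label, []).append(ep)
    out = {}
    for cond, eps in by_cond.items():
        shapes = {e.data.shape for e in eps}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch within condition {cond!r}")
        mean = np.mean([e.data for e in eps], axis=0)
        out[cond] = Epoch(mean, eps[0].rate_hz, list(eps[0].channel_names),
                          duration_s=eps[0].duration_s, condition_label=cond)
    return out


def amplitude_spectrum(epoch: Epoch) -> AmplitudeSpectrum:
    """Single-sided amplitude spectrum with a rectangular window."""
    n = epoch.n_samples
    spec = np.fft.rfft(epoch.data, axis=1)
    amp = np.abs(spec) / n
    amp[:, 1:] *= 2.0
    if n % 2 == 0:
        amp[:, -1] /= 2.0  # Nyquist bin is not duplicated
    return AmplitudeSpectrum(
        amp,
        bin_width_hz=1.0 / epoch.duration_s,
        rate_hz=epoch.rate_hz,
        channel_names=list(epoch.channel_names),
        kind="raw",
        condition_label=epoch.condition_label,
    )


def _neighbor_offsets(recipe: NoiseRecipe) -> np.ndarray:
    """Signed offsets of the neighborhood (post adjacent-exclusion)."""
    offs = np.arange(recipe.exclude_adjacent + 1, recipe.side_bins + 1)
    return np.concatenate([-offs[::-1], offs])


def _noise_values(
    row: np.ndarray, target_bin: int, recipe: NoiseRecipe
) -> tuple[np.ndarray, float]:
    """Reduced neighbor values for one channel row plus the baseline the
    detrend line predicts at the target bin (0 without detrending).

    The noise mean used downstream is ``trend_at_target + mean(values)``:
    detrending estimates deviations around the local linear trend, so the
    trend's value at offset 0 is part of the baseline.
    """
    offsets = _neighbor_offsets(recipe)
    vals = row[target_bin + offsets]
    trend_at_target = 0.0

    if recipe.detrend_range is not None:
        lo, hi = recipe.detrend_range
        fit_mask = (np.abs(offsets) >= lo) & (np.abs(offsets) <= hi)
        slope, intercept = np.polyfit(offsets[fit_mask], vals[fit_mask], 1)
        vals = vals - (slope * offsets + intercept)
        trend_at_target = float(intercept)

    if recipe.z_range is not None:
        lo, hi = recipe.z_range
        keep = (np.abs(offsets) >= lo) & (np.abs(offsets) <= hi)
        vals = vals[keep]

    if recipe.exclude_extremes and len(vals) > 2:
        drop = {int(np.argmax(vals)), int(np.argmin(vals))}
        if len(drop) == 1:  # all-equal neighborhood: still drop two values
            drop.add((int(np.argmax(vals)) + 1) % len(vals))
        vals = np.delete(vals, list(drop))
    return vals, trend_at_target


def noise_stats(
    spectrum: AmplitudeSpectrum,
    target_bin: int,
    recipe: NoiseRecipe,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel noise mean and SD around ``target_bin``.

    Returns ``(noise_mean, noise_sd, flat_flag)``; ``flat_flag`` marks
    channels whose noise SD is exactly 0 (downstream Z becomes +inf).
    """
    if target_bin - recipe.side_bins < 0 or \
            target_bin + recipe.side_bins >= spectrum.n_bins:
        raise ValueError(
            f"target bin {target_bin} lacks a {recipe.side_bins}-bin margin"
        )
    n_ch = spectrum.n_channels
    mean = np.empty(n_ch)
    sd = np.empty(n_ch)
    for ch in range(n_ch):
        vals, trend = _noise_values(spectrum.amplitudes[ch], target_bin, recipe)
        mean[ch] = trend + vals.mean()
        sd[ch] = vals.std(ddof=1)
    flag = sd == 0
    return mean, sd, flag


def correct_and_zscore(
    spectrum: AmplitudeSpectrum,
    recipe: NoiseRecipe,
    bins: np.ndarray | None = None,
) -> tuple[AmplitudeSpectrum, AmplitudeSpectrum]:
    """Baseline-corrected amplitudes and Z-scores, per bin per channel.

    ``corrected = amplitude - noise_mean`` (negative values preserved) and
    ``Z = corrected / noise_sd``. Bins without a full noise margin (or all
    bins outside ``bins`` if given) are NaN. Channels with zero noise SD get
    a +/-inf Z sentinel.
    """
    if spectrum.kind != "raw":
        raise ValueError("correct_and_zscore expects a raw spectrum")
    n_ch, n_bins = spectrum.amplitudes.shape
    corrected = np.full((n_ch, n_bins), np.nan)
    zscores = np.full((n_ch, n_bins), np.nan)
    if bins is None:
        bins = np.arange(recipe.side_bins, n_bins - recipe.side_bins)
    for b in bins:
        mean, sd, flag = noise_stats(spectrum, int(b), recipe)
        diff = spectrum.amplitudes[:, b] - mean
        corrected[:, b] = diff
        with np.errstate(divide="ignore", invalid="ignore"):
            z = diff / sd
            z[flag] = np.sign(diff[flag]) * Z_INF
        z[flag & (diff == 0)] = 0.0
        zscores[:, b] = z
    corr_spec = AmplitudeSpectrum(
        corrected, spectrum.bin_width_hz, spectrum.rate_hz,
        list(spectrum.channel_names), kind="baseline-corrected",
        condition_label=spectrum.condition_label,
    )
    z_spec = AmplitudeSpectrum(
        zscores, spectrum.bin_width_hz, spectrum.rate_hz,
        list(spectrum.channel_names), kind="z-scored",
        condition_label=spectrum.condition_label,
    )
    return corr_spec, z_spec


def zscore_at(
    spectrum: AmplitudeSpectrum, freq_hz: float, recipe: NoiseRecipe
) -> np.ndarray:
    """Per-channel Z at the bin nearest ``freq_hz`` (raw spectrum input)."""
    b = spectrum.bin_of(freq_hz)
    mean, sd, flag = noise_stats(spectrum, b, recipe)
    diff = spectrum.amplitudes[:, b] - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / sd
        z[flag] = np.sign(diff[flag]) * Z_INF
    z[flag & (diff == 0)] = 0.0
    return z


def select_harmonics(
    group_z_by_condition: dict[str, AmplitudeSpectrum],
    fundamental_hz: float,
    overlap_fundamental_hz: float | None = None,
    z_threshold: float = 1.64,
    max_hz: float = 50.0,
) -> HarmonicSet:
    """Retain the longest run of consecutively significant harmonics.

    Per condition, harmonics 1, 2, 3, ... of ``fundamental_hz`` are walked
    upward; harmonics coinciding with a multiple of
    ``overlap_fundamental_hz`` are skipped (they neither count nor break the
    run); the run ends at the first non-skipped harmonic with Z <=
    ``z_threshold`` or above ``max_hz``. The maximum run over conditions is
    retained. Z spectra must be single-channel (all-channel average).
    """
    if not group_z_by_condition:
        raise ValueError("no conditions given")

    def overlaps(k: int) -> bool:
        if overlap_fundamental_hz is None:
            return False
        ratio = k * fundamental_hz / overlap_fundamental_hz
        return abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1

    best_last = 0
    for cond, zspec in group_z_by_condition.items():
        if zspec.n_channels != 1:
            raise ValueError(
                f"condition {cond!r}: Z spectrum must be the all-channel average"
            )
        last = 0
        k = 0
        while True:
            k += 1
            f = k * fundamental_hz
            if f > max_hz + 1e-9:
                break
            if overlaps(k):
                continue
            b = int(round(f / zspec.bin_width_hz))
            if b >= zspec.n_bins:
                break
            z = zspec.amplitudes[0, b]
            if np.isnan(z) or z <= z_threshold:
                break
            last = k
        best_last = max(best_last, last)

    retained = [k for k in range(1, best_last + 1) if not overlaps(k)]
    excluded = [k for k in range(1, best_last + 1) if overlaps(k)]
    return HarmonicSet(
        fundamental_hz=fundamental_hz,
        retained_indices=retained,
        excluded_overlaps=excluded,
        flagged_empty=not retained,
    )


def harmonic_range(
    fundamental_hz: float,
    max_hz: float,
    overlap_fundamental_hz: float | None = None,
) -> HarmonicSet:
    """All harmonics of ``fundamental_hz`` up to ``max_hz`` inclusive,
    minus overlaps with ``overlap_fundamental_hz`` multiples."""
    ks = []
    excluded = []
    k = 0
    while True:
        k += 1
        f = k * fundamental_hz
        if f > max_hz + 1e-9:
            break
        if overlap_fundamental_hz is not None:
            ratio = f / overlap_fundamental_hz
            if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
                excluded.append(k)
                continue
        ks.append(k)
    return HarmonicSet(fundamental_hz, ks, excluded)


def sum_harmonic_chunks(
    spectrum: AmplitudeSpectrum,
    harmonic_set: HarmonicSet,
    recipe: NoiseRecipe,
) -> SummedResponse:
    """Sum spectrum chunks centered on each retained harmonic, then apply
    the noise correction to the summed chunk's center bin.

    The summed corrected amplitude is the sum of the per-harmonic
    baseline-corrected amplitudes (exactly linear). The Z statistic is
    computed by applying the noise recipe to the element-wise summed chunk
    (the two differ microscopically because the max/min exclusion may drop
    different offsets per harmonic).
    """
    if spectrum.kind != "raw":
        raise ValueError("sum_harmonic_chunks expects a raw spectrum")
    if not harmonic_set.retained_indices:
        raise ValueError("empty harmonic set")
    w = recipe.side_bins
    chunks = []
    corrected_sum = np.zeros(spectrum.n_channels)
    for k in harmonic_set.retained_indices:
        f = k * harmonic_set.fundamental_hz
        b = spectrum.bin_of(f)
        if b - w < 0 or b + w >= spectrum.n_bins:
            raise ValueError(
                f"harmonic {k} ({f} Hz) lacks a {w}-bin noise margin"
            )
        chunks.append(spectrum.amplitudes[:, b - w:b + w + 1])
        mean_k, _, _ = noise_stats(spectrum, b, recipe)
        corrected_sum += spectrum.amplitudes[:, b] - mean_k
    summed = np.sum(chunks, axis=0)

    chunk_spec = AmplitudeSpectrum(
        summed, spectrum.bin_width_hz, spectrum.rate_hz,
        list(spectrum.channel_names), kind="raw",
        condition_label=spectrum.condition_label,
    )
    mean, sd, flag = noise_stats(chunk_spec, w, recipe)
    chunk_diff = summed[:, w] - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = chunk_diff / sd
        z[flag] = np.sign(chunk_diff[flag]) * Z_INF
    z[flag & (chunk_diff == 0)] = 0.0
    return SummedResponse(
        amplitude_uv=corrected_sum,
        z=z,
        channel_names=list(spectrum.channel_names),
        harmonic_set=harmonic_set,
        condition_label=spectrum.condition_label,
        summed_chunk=summed,
    )
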