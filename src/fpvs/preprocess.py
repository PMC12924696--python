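"""Preprocessing chains for adult and infant recordings.

Filtering, resampling, segmentation, blink-component removal, amplitude
artifact blocking, bad-channel interpolation and symmetric-average
re-referencing. All operators are shape-preserving except :func:`resample`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import RawRecording, Segment
from .montage import Montage

__all__ = [
    "bandpass_filter",
    "resample",
    "crop_segments",
    "remove_blink_components",
    "artifact_block",
    "interpolate_channels",
    "rereference_symmetric_average",
    "BlinkReport",
    "ArtifactReport",
]

log = logging.getLogger(__name__)


@dataclass
class BlinkReport:
    """What the blink-removal operator did to one segment."""

    removed_components: list[int] = field(default_factory=list)
    n_components_fit: int = 0
    error: str | None = None

    @property
    def n_removed(self) -> int:
        return len(self.removed_components)


@dataclass
class ArtifactReport:
    """What the amplitude-blocking operator did to one segment."""

    n_marked_samples: int = 0
    marked_fraction: float = 0.0
    residual_fraction: float = 0.0   # samples still above threshold afterwards
    channels_affected: list[str] = field(default_factory=list)
    unusable: bool = False


def bandpass_filter(
    recording: RawRecording,
    low_hz: float = 0.1,
    high_hz: float = 100.0,
    order: int = 4,
) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth bandpass per channel."""
    nyq = recording.rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) must satisfy "
            f"0 < low < high < Nyquist ({nyq})"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=recording.rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy_with(data=out)


def resample(recording: RawRecording, target_hz: float = 200.0) -> RawRecording:
    """Polyphase anti-aliased downsampling to ``target_hz``."""
    if target_hz >= recording.rate_hz:
        raise ValueError("upsampling is not supported")
    frac = Fraction(target_hz / recording.rate_hz).limit_denominator(1000)
    out = signal.resample_poly(recording.data, frac.numerator,
                               frac.denominator, axis=1)
    scale = target_hz / recording.rate_hz
    events = [(t, lab) for t, lab in recording.events]
    expected = int(round(recording.n_samples * scale))
    out = out[:, :expected] if out.shape[1] >= expected else out
    return RawRecording(out, target_hz, list(recording.channel_names), events)


def crop_segments(recording: RawRecording, duration_s: float = 36.0) -> list[Segment]:
    """One segment per sequence-onset event; segments that would run past
    the end of the recording are dropped with a warning."""
    n = int(round(duration_s * recording.rate_hz))
    segments = []
    for t, label in recording.events:
        i0 = int(round(t * recording.rate_hz))
        if i0 + n > recording.n_samples:
            log.warning(
                "dropping segment at %.3f s (%r): exceeds recording end", t, label
            )
            continue
        segments.append(
            Segment(
                recording.data[:, i0:i0 + n].copy(),
                recording.rate_hz,
                list(recording.channel_names),
                condition_label=label,
                t0_s=t,
            )
        )
    return segments


def _blink_band_envelope(
    segment: Segment, frontal_idx: np.ndarray
) -> np.ndarray:
    """Mean frontal signal lowpassed to the blink band (0.5-4 Hz)."""
    front = segment.data[frontal_idx].mean(axis=0)
    sos = signal.butter(4, [0.5, 4.0], btype="bandpass",
                        fs=segment.rate_hz, output="sos")
    return signal.sosfiltfilt(sos, front)


def remove_blink_components(
    segment: Segment,
    montage: Montage,
    max_components: int = 5,
    frontal_threshold_uv: float = 200.0,
) -> tuple[Segment, BlinkReport]:
    """Fit a linear decomposition and remove blink-like components.

    A component is flagged when its back-projection exceeds
    ``frontal_threshold_uv`` on frontal/central channels, or when its time
    course correlates > 0.7 with the frontal blink-band envelope. At most
    ``max_components`` are removed. On decomposition failure the segment is
    returned unchanged with an error flag.
    """
    if segment.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if segment.duration_s < 10:
        raise ValueError("segment too short for a stable decomposition")

    frontal = [c for c in montage.frontal_central() if c in segment.channel_names]
    frontal_idx = np.array([segment.channel_names.index(c) for c in frontal])

    x = segment.data
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    try:
        from sklearn.decomposition import FastICA

        # full-rank decomposition: dimensionality reduction mixes blink
        # variance into retained components and hurts posterior recovery
        ica = FastICA(n_components=None, random_state=0, max_iter=500,
                      whiten="unit-variance", tol=1e-3)
        sources = ica.fit_transform(xc.T).T          # (n_comp, n_samples)
        mixing = ica.mixing_                          # (n_channels, n_comp)
    except Exception as exc:  # pragma: no cover - depends on solver behavior
        return segment, BlinkReport(error=f"decomposition failed: {exc}")

    envelope = _blink_band_envelope(segment, frontal_idx)
    env_sd = envelope.std()

    scores = []
    for k in range(sources.shape[0]):
        back = np.outer(mixing[:, k], sources[k])
        frontal_peak = np.abs(back[frontal_idx]).max() if len(frontal_idx) else 0.0
        if env_sd > 0 and sources[k].std() > 0:
            corr = abs(np.corrcoef(sources[k], envelope)[0, 1])
        else:
            corr = 0.0
        flagged = frontal_peak > frontal_threshold_uv or corr > 0.7
        scores.append((flagged, frontal_peak, corr, k))

    flagged = [s for s in scores if s[0]]
    flagged.sort(key=lambda s: (s[1], s[2]), reverse=True)
    removed = [s[3] for s in flagged[:max_components]]

    if removed:
        cleaned_sources = sources.copy()
        cleaned_sources[removed] = 0.0
        out = mixing @ cleaned_sources + mean
    else:
        out = x.copy()
    report = BlinkReport(removed_components=removed,
                         n_components_fit=sources.shape[0])
    return segment.copy_with(data=out), report


def artifact_block(
    segment: Segment, threshold_uv: float = 500.0
) -> tuple[Segment, ArtifactReport]:
    """Suppress high-amplitude stretches by spatial reconstruction.

    Samples with ``|value| > threshold_uv`` (padded by 50 ms on each side)
    are marked per channel. Each affected channel is re-estimated inside its
    marked stretches by a least-squares spatial projection from the
    simultaneously unmarked channels, fit on artifact-free samples.
    Unmarked samples are returned untouched.
    """
    if segment.n_channels < 2:
        raise ValueError("need at least 2 channels")
    x = segment.data
    mask = np.abs(x) > threshold_uv
    report = ArtifactReport()
    if not mask.any():
        return segment.copy_with(data=x.copy()), report

    pad = int(round(0.05 * segment.rate_hz))
    if pad:
        kernel = np.ones(2 * pad + 1, dtype=bool)
        mask = np.apply_along_axis(
            lambda m: np.convolve(m, kernel, mode="same") > 0, 1, mask
        )

    frac = mask.mean()
    report.n_marked_samples = int(mask.sum())
    report.marked_fraction = float(frac)
    if frac > 0.5:
        report.unusable = True
        return segment.copy_with(data=x.copy()), report

    clean_cols = ~mask.any(axis=0)
    out = x.copy()
    names = segment.channel_names
    for ch in range(segment.n_channels):
        marked = mask[ch]
        if not marked.any():
            continue
        report.channels_affected.append(names[ch])
        others = [j for j in range(segment.n_channels) if j != ch]
        if clean_cols.sum() >= len(others) + 2:
            a = x[np.ix_(others, np.where(clean_cols)[0])].T
            b = x[ch, clean_cols]
            coef, *_ = np.linalg.lstsq(
                np.column_stack([a, np.ones(len(a))]), b, rcond=None
            )
            cols = np.where(marked)[0]
            pred = x[np.ix_(others, cols)].T @ coef[:-1] + coef[-1]
        else:
            pred = np.zeros(marked.sum())
        # other channels may themselves be artifactual at these samples;
        # cap the reconstruction so blocked output respects the threshold
        pred = np.clip(pred, -threshold_uv, threshold_uv)
        out[ch, marked] = pred

    residual = np.abs(out) > threshold_uv
    report.residual_fraction = float(residual.mean())
    return segment.copy_with(data=out), report


def interpolate_channels(
    segment: Segment,
    bad_channels: list[str],
    montage: Montage,
    k: int = 4,
) -> Segment:
    """Replace bad channels by the inverse-distance-weighted average of
    their ``k`` nearest good channels."""
    if not bad_channels:
        return segment.copy_with(data=segment.data.copy())
    unknown = [c for c in bad_channels if c not in segment.channel_names]
    if unknown:
        raise ValueError(f"bad channels not in segment: {unknown}")
    good = [c for c in segment.channel_names if c not in bad_channels]
    if len(good) < 3:
        raise ValueError("need at least 3 good channels to interpolate")

    out = segment.data.copy()
    pos = {c: montage.positions[montage.index(c)] for c in segment.channel_names}
    for bad in bad_channels:
        d = np.array([np.linalg.norm(pos[bad] - pos[g]) for g in good])
        order = np.argsort(d)[:k]
        dist = np.maximum(d[order], 1e-12)
        w = 1.0 / dist
        w = w / w.sum()
        idx = [segment.channel_names.index(good[i]) for i in order]
        out[segment.channel_names.index(bad)] = w @ segment.data[idx]
    return segment.copy_with(data=out)


def rereference_symmetric_average(segment: Segment, montage: Montage) -> Segment:
    """Re-reference to the mean over mirror-paired + midline channels.

    Channels without a mirror partner and off the midline are excluded from
    the reference but still re-referenced. Post hoc, the mean over the
    reference set is 0 at every sample.
    """
    if not montage.mirror_pairs:
        raise ValueError("montage has no mirror pairs")
    ref_names = [c for c in montage.symmetric_set() if c in segment.channel_names]
    if not ref_names:
        raise ValueError("empty reference set")
    idx = [segment.channel_names.index(c) for c in ref_names]
    ref = segment.data[idx].mean(axis=0)
    return segment.copy_with(data=segment.data - ref[None, :])
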