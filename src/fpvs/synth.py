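"""Synthetic FPVS-EEG generation with known ground truth.

Builds stimulation schedules (fast base rate with a periodic oddball),
steady-state harmonic components with channel topographies, 1/f noise,
blink/spike artifacts, and whole cohorts with condition x group effects
on the oddball amplitude. Also provides the Fourier phase-scrambling
image control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import RawRecording
from .montage import Montage

__all__ = [
    "StimulusSchedule",
    "SteadyStateComponent",
    "NoiseModel",
    "CohortDesign",
    "GroundTruthManifest",
    "build_sequence_schedule",
    "phase_scramble_image",
    "simulate_recording",
    "simulate_cohort",
    "oddball_component",
    "base_component",
]


@dataclass
class StimulusSchedule:
    """Onsets, oddball flags and contrast envelope of one FPVS sequence."""

    base_rate: float
    oddball_period: int
    fade_in_s: float
    full_s: float
    fade_out_s: float
    onsets: np.ndarray
    oddball_flags: np.ndarray
    contrast: np.ndarray
    warning: str | None = None

    @property
    def total_duration_s(self) -> float:
        return self.fade_in_s + self.full_s + self.fade_out_s

    @property
    def oddball_hz(self) -> float:
        return self.base_rate / self.oddball_period

    @property
    def n_stimuli(self) -> int:
        return len(self.onsets)

    def contrast_envelope(self, t: np.ndarray) -> np.ndarray:
        """Per-sample contrast in [0, 1]: linear 0->1 ramp over the fade-in,
        1 during full-contrast stimulation, 1->0 over the fade-out."""
        t = np.asarray(t, dtype=float)
        env = np.ones_like(t)
        if self.fade_in_s > 0:
            m = t < self.fade_in_s
            env[m] = t[m] / self.fade_in_s
        if self.fade_out_s > 0:
            t1 = self.fade_in_s + self.full_s
            m = t >= t1
            env[m] = np.clip(1.0 - (t[m] - t1) / self.fade_out_s, 0.0, 1.0)
        env[t < 0] = 0.0
        env[t > self.total_duration_s] = 0.0
        return env


@dataclass
class SteadyStateComponent:
    """A harmonic series response (fundamental + harmonics) with a scalp
    topography; amplitudes are in μV at full contrast."""

    fundamental_hz: float
    harmonic_amplitudes: np.ndarray   # amplitude of harmonic k = k-th entry
    harmonic_phases: np.ndarray | None = None
    topography: np.ndarray | None = None  # per-channel weight in [0, 1]
    name: str = ""

    def __post_init__(self) -> None:
        self.harmonic_amplitudes = np.asarray(self.harmonic_amplitudes, dtype=float)
        if np.any(self.harmonic_amplitudes < 0):
            raise ValueError("harmonic amplitudes must be >= 0")
        if self.fundamental_hz <= 0:
            raise ValueError("fundamental_hz must be positive")
        if self.harmonic_phases is None:
            self.harmonic_phases = np.zeros_like(self.harmonic_amplitudes)
        else:
            self.harmonic_phases = np.asarray(self.harmonic_phases, dtype=float)
        if self.topography is not None:
            self.topography = np.asarray(self.topography, dtype=float)
            if not np.any(self.topography):
                raise ValueError("topography needs at least one nonzero weight")

    @property
    def max_freq_hz(self) -> float:
        return self.fundamental_hz * len(self.harmonic_amplitudes)


@dataclass
class NoiseModel:
    """Background noise and artifact parameters."""

    pink_exponent: float = 1.0
    noise_scale: float = 0.0      # μV RMS per channel
    blink_rate: float = 0.0       # events / min
    blink_amplitude: float = 0.0  # μV peak
    spike_rate: float = 0.0       # events / min
    spike_amplitude: float = 0.0  # μV

    def __post_init__(self) -> None:
        for name in ("noise_scale", "blink_rate", "blink_amplitude",
                     "spike_rate", "spike_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CohortDesign:
    """Condition x age-group amplitude structure for a simulated cohort."""

    n_per_group: int
    conditions: list[str]
    groups: list[str]
    oddball_mean_by_cell: dict[tuple[str, str], float]  # (condition, group) -> μV
    between_sd: float
    within_sd: float
    trials_per_condition: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2 for the stats layer")
        for c in self.conditions:
            for g in self.groups:
                if (c, g) not in self.oddball_mean_by_cell:
                    raise ValueError(f"missing cell mean for {(c, g)}")


@dataclass
class GroundTruthManifest:
    """Everything needed to reconstruct the noise-free signal."""

    seed: int
    component_amplitudes: dict[str, list[float]] = field(default_factory=dict)
    blink_times_s: list[float] = field(default_factory=list)
    spike_times_s: list[float] = field(default_factory=list)
    clean_data: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def build_sequence_schedule(
    base_rate: float,
    oddball_period: int,
    fade_in_s: float,
    full_s: float,
    fade_out_s: float,
) -> StimulusSchedule:
    """Build one stimulation sequence schedule.

    Every ``oddball_period``-th stimulus is the oddball (the paradigm shows
    it as the last stimulus of each oddball cycle). Stimulus count is
    ``round(total_duration * base_rate)``.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if oddball_period < 2:
        raise ValueError("oddball_period must be >= 2")
    if min(fade_in_s, full_s, fade_out_s) < 0:
        raise ValueError("durations must be >= 0")
    total = fade_in_s + full_s + fade_out_s
    n = int(round(total * base_rate))
    onsets = np.arange(n) / base_rate
    flags = (np.arange(n) + 1) % oddball_period == 0
    warning = None
    oddball_hz = base_rate / oddball_period
    n_cycles = full_s * oddball_hz
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        warning = (
            f"full-contrast duration {full_s} s is not an integer number of "
            f"{1 / oddball_hz:.3f}-s oddball cycles"
        )
        warnings.warn(warning, stacklevel=2)
    sched = StimulusSchedule(
        base_rate=base_rate,
        oddball_period=oddball_period,
        fade_in_s=fade_in_s,
        full_s=full_s,
        fade_out_s=fade_out_s,
        onsets=onsets,
        oddball_flags=flags,
        contrast=np.empty(0),
        warning=warning,
    )
    sched.contrast = sched.contrast_envelope(onsets)
    return sched


def phase_scramble_image(image: np.ndarray, seed: int) -> np.ndarray:
    """Replace an image's Fourier phase by random coefficients, exactly
    preserving the amplitude spectrum (per color plane) and the mean.

    Random phases are taken from the FFT of a white-noise field, which
    satisfies the conjugate-symmetry constraint so the output is real.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        rng = np.random.default_rng(seed)
        planes = [
            _scramble_plane(image[..., k], np.random.default_rng(rng.integers(2**63)))
            for k in range(image.shape[2])
        ]
        return np.stack(planes, axis=-1)
    if image.ndim != 2:
        raise ValueError("image must be 2-D (per color plane)")
    return _scramble_plane(image, np.random.default_rng(seed))


def _scramble_plane(plane: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.fft2(plane)
    noise = rng.standard_normal(plane.shape)
    phase = np.angle(np.fft.fft2(noise))
    phase[0, 0] = np.angle(spec[0, 0])  # keep the mean exactly
    out = np.fft.ifft2(np.abs(spec) * np.exp(1j * phase)).real
    return out


def frontal_topography(montage: Montage) -> np.ndarray:
    """Blink-like topography: strong on anterior channels, fading to zero
    posteriorly (weight from the schematic y coordinate)."""
    y = montage.positions[:, 1]
    w = np.clip((y - 0.1) / 0.9, 0.0, 1.0)
    return w


def posterior_topography(montage: Montage, right_bias: float = 0.0) -> np.ndarray:
    """Occipito-temporal topography for visual responses; ``right_bias`` in
    [0, 1] shifts weight toward right-hemisphere channels."""
    x, y = montage.positions[:, 0], montage.positions[:, 1]
    w = np.clip((-y - 0.1) / 0.9, 0.0, 1.0)
    if right_bias:
        w = w * (1.0 + right_bias * np.clip(x, 0.0, 1.0))
    m = w.max()
    return w / m if m > 0 else w


def oddball_component(
    amplitude_uv: float,
    montage: Montage,
    harmonic_falloff: float = 0.5,
    n_harmonics: int = 4,
    oddball_hz: float = 1.0,
    right_bias: float = 0.6,
    phases: np.ndarray | None = None,
) -> SteadyStateComponent:
    """Oddball (e.g. face-selective) harmonic series; the fundamental has
    ``amplitude_uv`` and each next harmonic falls off geometrically."""
    amps = amplitude_uv * harmonic_falloff ** np.arange(n_harmonics)
    return SteadyStateComponent(
        fundamental_hz=oddball_hz,
        harmonic_amplitudes=amps,
        harmonic_phases=phases,
        topography=posterior_topography(montage, right_bias=right_bias),
        name="oddball",
    )


def base_component(
    amplitude_uv: float,
    montage: Montage,
    harmonic_falloff: float = 0.6,
    n_harmonics: int = 3,
    base_hz: float = 6.0,
    phases: np.ndarray | None = None,
) -> SteadyStateComponent:
    """General visual response at the base stimulation rate."""
    amps = amplitude_uv * harmonic_falloff ** np.arange(n_harmonics)
    return SteadyStateComponent(
        fundamental_hz=base_hz,
        harmonic_amplitudes=amps,
        harmonic_phases=phases,
        topography=posterior_topography(montage, right_bias=0.0),
        name="base",
    )


def _pink_noise(
    n_channels: int, n_samples: int, rate_hz: float, alpha: float,
    rms_uv: float, rng: np.random.Generator,
) -> np.ndarray:
    """1/f^alpha noise, independent per channel, scaled to rms_uv."""
    if rms_uv == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1 / rate_hz)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1) * shaping
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = noise.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return noise / rms * rms_uv


def _blink_template(rate_hz: float) -> np.ndarray:
    """300-ms half-cosine bump, unit peak."""
    n = max(int(round(0.3 * rate_hz)), 3)
    return np.sin(np.pi * np.arange(n) / (n - 1))


def simulate_recording(
    schedule: StimulusSchedule,
    components: list[SteadyStateComponent],
    noise_model: NoiseModel,
    montage: Montage,
    rate_hz: float = 1000.0,
    n_sequences: int = 1,
    seed: int = 0,
    inter_sequence_gap_s: float = 2.0,
    condition_labels: list[str] | None = None,
) -> tuple[RawRecording, GroundTruthManifest]:
    """Simulate a continuous recording of ``n_sequences`` FPVS sequences.

    Each component contributes a sum of cosines at k x fundamental, scaled
    per channel by its topography and per sample by the contrast envelope.
    Pink noise, blinks and spikes are added on top. Event markers are placed
    at each sequence onset.
    """
    for comp in components:
        if rate_hz < 2 * comp.max_freq_hz:
            raise ValueError(
                f"rate {rate_hz} Hz violates Nyquist for component "
                f"{comp.name!r} (max {comp.max_freq_hz} Hz)"
            )
    if schedule.total_duration_s <= 0:
        raise ValueError("zero-duration schedule")

    rng = np.random.default_rng(seed)
    n_ch = montage.n_channels
    seq_dur = schedule.total_duration_s
    period = seq_dur + inter_sequence_gap_s
    total_s = n_sequences * period + inter_sequence_gap_s
    n_samples = int(round(total_s * rate_hz))
    clean = np.zeros((n_ch, n_samples))
    events: list[tuple[float, str]] = []
    if condition_labels is None:
        condition_labels = ["seq"] * n_sequences

    n_seq_samples = int(round(seq_dur * rate_hz))
    t_seq = np.arange(n_seq_samples) / rate_hz
    env = schedule.contrast_envelope(t_seq)

    seq_signal = np.zeros((n_ch, n_seq_samples))
    for comp in components:
        topo = (np.ones(n_ch) if comp.topography is None
                else np.asarray(comp.topography, dtype=float))
        wave = np.zeros(n_seq_samples)
        for k, (amp, ph) in enumerate(
            zip(comp.harmonic_amplitudes, comp.harmonic_phases), start=1
        ):
            wave += amp * np.cos(2 * np.pi * k * comp.fundamental_hz * t_seq + ph)
        seq_signal += topo[:, None] * (wave * env)[None, :]

    onsets_s = []
    for i in range(n_sequences):
        t0 = inter_sequence_gap_s + i * period
        onsets_s.append(t0)
        i0 = int(round(t0 * rate_hz))
        clean[:, i0:i0 + n_seq_samples] += seq_signal
        events.append((t0, condition_labels[i]))

    data = clean + _pink_noise(
        n_ch, n_samples, rate_hz, noise_model.pink_exponent,
        noise_model.noise_scale, rng,
    )

    blink_times: list[float] = []
    if noise_model.blink_rate > 0 and noise_model.blink_amplitude > 0:
        n_blinks = rng.poisson(noise_model.blink_rate * total_s / 60.0)
        template = _blink_template(rate_hz)
        topo = frontal_topography(montage)
        for _ in range(n_blinks):
            t = rng.uniform(0, total_s - 0.31)
            i0 = int(round(t * rate_hz))
            end = i0 + len(template)
            if end > n_samples:
                continue
            data[:, i0:end] += (
                noise_model.blink_amplitude * topo[:, None] * template[None, :]
            )
            blink_times.append(t)

    spike_times: list[float] = []
    if noise_model.spike_rate > 0 and noise_model.spike_amplitude > 0:
        n_spikes = rng.poisson(noise_model.spike_rate * total_s / 60.0)
        for _ in range(n_spikes):
            t = rng.uniform(0, total_s)
            i0 = min(int(round(t * rate_hz)), n_samples - 1)
            ch = rng.integers(n_ch)
            data[ch, i0] += noise_model.spike_amplitude * rng.choice([-1.0, 1.0])
            spike_times.append(t)

    recording = RawRecording(data, rate_hz, list(montage.channel_names), events)
    manifest = GroundTruthManifest(
        seed=seed,
        component_amplitudes={
            c.name or f"component{i}": list(c.harmonic_amplitudes)
            for i, c in enumerate(components)
        },
        blink_times_s=blink_times,
        spike_times_s=spike_times,
        clean_data=clean,
        extra={"sequence_onsets_s": onsets_s, "rate_hz": rate_hz},
    )
    return recording, manifest


def draw_cohort_amplitudes(design: CohortDesign) -> dict:
    """Draw per-participant, per-condition, per-trial oddball amplitudes:
    cell mean + participant effect (between_sd) + trial noise (within_sd),
    truncated at 0. Returns a nested dict keyed by participant id."""
    rng = np.random.default_rng(design.seed)
    out: dict[str, dict] = {}
    pid = 0
    for group in design.groups:
        for _ in range(design.n_per_group):
            name = f"sub{pid:03d}"
            pid += 1
            part_effect = rng.normal(0.0, design.between_sd)
            trials = {}
            for cond in design.conditions:
                mu = design.oddball_mean_by_cell[(cond, group)]
                vals = mu + part_effect + rng.normal(
                    0.0, design.within_sd, design.trials_per_condition
                )
                trials[cond] = np.clip(vals, 0.0, None)
            out[name] = {"group": group, "amplitudes": trials}
    return out


def simulate_cohort(
    design: CohortDesign,
    montage: Montage,
    schedule: StimulusSchedule,
    noise_model: NoiseModel,
    rate_hz: float = 200.0,
    base_amplitude_uv: float = 2.0,
    n_oddball_harmonics: int = 4,
) -> tuple[dict[str, RawRecording], GroundTruthManifest]:
    """Simulate a full cohort of recordings following ``design``.

    One recording per participant; its sequences interleave the conditions,
    with the oddball fundamental amplitude drawn per trial.
    """
    draws = draw_cohort_amplitudes(design)
    rng = np.random.default_rng(design.seed + 1)
    recordings: dict[str, RawRecording] = {}
    manifest = GroundTruthManifest(seed=design.seed)
    manifest.extra["participants"] = {}

    for name, info in draws.items():
        labels: list[str] = []
        amps: list[float] = []
        for trial in range(design.trials_per_condition):
            for cond in design.conditions:
                labels.append(cond)
                amps.append(float(info["amplitudes"][cond][trial]))
        pieces = []
        events: list[tuple[float, str]] = []
        gap = 1.0
        t_cursor = gap
        for lab, amp in zip(labels, amps):
            comps = [
                oddball_component(amp, montage, n_harmonics=n_oddball_harmonics),
                base_component(base_amplitude_uv, montage),
            ]
            rec, _ = simulate_recording(
                schedule, comps, noise_model, montage, rate_hz=rate_hz,
                n_sequences=1, seed=int(rng.integers(2**63)),
                inter_sequence_gap_s=gap, condition_labels=[lab],
            )
            pieces.append(rec.data)
            events.append((t_cursor, lab))
            t_cursor += rec.data.shape[1] / rate_hz
        data = np.concatenate(pieces, axis=1)
        recordings[name] = RawRecording(
            data, rate_hz, list(montage.channel_names), events
        )
        manifest.extra["participants"][name] = {
            "group": info["group"],
            "trial_labels": labels,
            "trial_amplitudes": amps,
        }
    return recordings, manifest
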