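"""Analysis configuration: two shipped presets freeze every adult and
infant pipeline parameter, plus YAML round-tripping and a provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "get_preset", "PRESETS"]


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs, serializable to YAML."""

    population: str = "adult"          # adult | infant
    montage: str = "adult"
    filter_low_hz: float = 0.1
    filter_high_hz: float = 100.0
    filter_order: int = 4
    resample_hz: float = 200.0
    segment_duration_s: float = 36.0
    epoch_offset_s: float = 0.833
    epoch_duration_s: float = 34.0
    oddball_hz: float = 1.0
    base_hz: float = 6.0
    noise_recipe: str = "adult"        # adult | infant
    z_threshold: float = 1.64
    max_harmonic_hz: float = 50.0
    # artifact handling
    blink_max_components: int = 5
    blink_frontal_threshold_uv: float = 200.0
    artifact_block_threshold_uv: float | None = None   # infant only
    # infant epoch screening
    screening_enabled: bool = False
    screening_channels: tuple[str, ...] = ("POz", "O1", "Oz", "O2")
    screening_freqs_hz: tuple[float, ...] = (6.0, 12.0)
    screening_z_threshold: float = 2.32
    # ROIs
    roi_preset_face: str = "adult_face"
    roi_preset_general: str = "adult_general"
    # conditions and stats plan
    conditions: tuple[str, ...] = ("classic_intact", "new_intact",
                                   "classic_scrambled", "new_scrambled")
    within_factors: tuple[str, ...] = ("set", "scrambling")
    between_factor: str | None = None
    bad_channels: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        n_cycles = self.epoch_duration_s * self.oddball_hz
        if abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError(
                "epoch duration must span an integer number of oddball cycles"
            )
        if self.population not in ("adult", "infant"):
            raise ValueError("population must be 'adult' or 'infant'")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        for key in ("screening_channels", "screening_freqs_hz", "conditions",
                    "within_factors", "bad_channels"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable content hash recorded in every output for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _adult_preset() -> AnalysisConfig:
    return AnalysisConfig(
        population="adult",
        montage="adult",
        noise_recipe="adult",
        roi_preset_face="adult_face",
        roi_preset_general="adult_general",
        screening_enabled=False,
        conditions=("classic_intact", "new_intact",
                    "classic_scrambled", "new_scrambled"),
        within_factors=("set", "scrambling"),
        between_factor=None,
    )


def _infant_preset() -> AnalysisConfig:
    return AnalysisConfig(
        population="infant",
        montage="infant",
        noise_recipe="infant",
        roi_preset_face="infant_face",
        roi_preset_general="infant_general",
        artifact_block_threshold_uv=500.0,
        screening_enabled=True,
        conditions=("classic", "new"),
        within_factors=("set",),
        between_factor="age",
    )


PRESETS = {
    "adult_exp1": _adult_preset,
    "infant_exp2": _infant_preset,
}


def get_preset(name: str) -> AnalysisConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name]()
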