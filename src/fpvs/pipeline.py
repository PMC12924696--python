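"""End-to-end orchestration: simulate/load -> preprocess -> spectral ->
ROI quantification -> group statistics, with CSV/JSON outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, quantify, spectral, stats
from .config import AnalysisConfig
from .core import RawRecording
from .montage import Montage, make_montage
from .spectral import ADULT_RECIPE, INFANT_RECIPE, HarmonicSet, NoiseRecipe

__all__ = ["PipelineResult", "run_pipeline", "preprocess_recording",
           "analyze_participant"]

log = logging.getLogger(__name__)


def _recipe(cfg: AnalysisConfig) -> NoiseRecipe:
    return INFANT_RECIPE if cfg.noise_recipe == "infant" else ADULT_RECIPE


@dataclass
class PipelineResult:
    """Tidy tables produced by one pipeline run."""

    config_hash: str
    roi_table: pd.DataFrame            # participant x condition x roi x response
    channel_table: pd.DataFrame        # per-channel summed amplitudes and Z
    screening_log: pd.DataFrame
    harmonic_sets: dict[str, HarmonicSet]
    anova_tables: dict[str, stats.AnovaTable] = field(default_factory=dict)
    group_z: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": self.config_hash,
                "harmonics": {
                    name: {"fundamental_hz": hs.fundamental_hz,
                           "retained": hs.retained_indices,
                           "excluded_overlaps": hs.excluded_overlaps}
                    for name, hs in self.harmonic_sets.items()
                }}
        (out / "run_info.json").write_text(json.dumps(meta, indent=2))
        self.roi_table.to_csv(out / "roi_responses.csv", index=False)
        self.channel_table.to_csv(out / "channel_responses.csv", index=False)
        self.screening_log.to_csv(out / "screening_log.csv", index=False)
        for name, at in self.anova_tables.items():
            at.table.to_csv(out / f"anova_{name}.csv", index=False)
        for name, gz in self.group_z.items():
            gz.to_csv(out / f"group_z_{name}.csv", index=False)
        return out


def preprocess_recording(
    recording: RawRecording, cfg: AnalysisConfig, montage: Montage
):
    """Run the population-appropriate preprocessing chain, returning clean
    segments and a per-segment report list."""
    # recordings already at/below the target rate need the upper edge pulled
    # inside their own Nyquist
    high = min(cfg.filter_high_hz, 0.45 * recording.rate_hz)
    rec = preprocess.bandpass_filter(
        recording, cfg.filter_low_hz, high, cfg.filter_order
    )
    if cfg.resample_hz < rec.rate_hz:
        rec = preprocess.resample(rec, cfg.resample_hz)
    segments = preprocess.crop_segments(rec, cfg.segment_duration_s)

    clean = []
    reports = []
    for seg in segments:
        if cfg.population == "adult":
            seg, rep = preprocess.remove_blink_components(
                seg, montage, cfg.blink_max_components,
                cfg.blink_frontal_threshold_uv,
            )
        else:
            thr = cfg.artifact_block_threshold_uv or 500.0
            seg, rep = preprocess.artifact_block(seg, thr)
            if getattr(rep, "unusable", False):
                reports.append(rep)
                continue
        if cfg.bad_channels:
            seg = preprocess.interpolate_channels(
                seg, list(cfg.bad_channels), montage
            )
        seg = preprocess.rereference_symmetric_average(seg, montage)
        clean.append(seg)
        reports.append(rep)
    return clean, reports


def analyze_participant(
    segments, cfg: AnalysisConfig, harmonic_sets: dict[str, HarmonicSet]
):
    """Epoch (+screen), average by condition, and quantify both responses.

    Returns (rows, screening_rows); one row per condition x response x
    channel with summed corrected amplitude and Z.
    """
    recipe = _recipe(cfg)
    epochs = []
    screening_rows = []
    for i, seg in enumerate(segments):
        ep = spectral.epoch_exact_cycles(
            seg, cfg.epoch_offset_s, cfg.epoch_duration_s, cfg.oddball_hz
        )
        if cfg.screening_enabled:
            spec = spectral.amplitude_spectrum(ep)
            decision = quantify.screen_epoch(
                spec, cfg.screening_channels, cfg.screening_freqs_hz,
                cfg.screening_z_threshold, INFANT_RECIPE,
            )
            screening_rows.append({
                "epoch": i, "condition": ep.condition_label,
                "keep": decision.keep, "max_z": decision.max_z,
                "channel": decision.best_channel,
                "freq_hz": decision.best_freq_hz,
            })
            if not decision.keep:
                continue
        epochs.append(ep)

    rows = []
    spectra_by_cond = {}
    if epochs:
        for cond, avg in spectral.average_epochs_by_condition(epochs).items():
            spec = spectral.amplitude_spectrum(avg)
            spectra_by_cond[cond] = spec
            for resp_name, hs in harmonic_sets.items():
                summed = spectral.sum_harmonic_chunks(spec, hs, recipe)
                for ch, amp, z in zip(summed.channel_names,
                                      summed.amplitude_uv, summed.z):
                    rows.append({
                        "condition": cond, "response": resp_name,
                        "channel": ch, "amplitude_uv": float(amp),
                        "z": float(z),
                    })
    return rows, screening_rows, spectra_by_cond


def default_harmonic_sets(cfg: AnalysisConfig) -> dict[str, HarmonicSet]:
    """The study's fixed harmonic ranges: oddball 1 Hz up to 15 Hz for
    adults / 4 Hz for infants (base-rate overlaps excluded), and the base
    response up to 48 Hz."""
    if cfg.population == "adult":
        oddball_max = 15.0
    else:
        oddball_max = 4.0
    return {
        "oddball": spectral.harmonic_range(
            cfg.oddball_hz, oddball_max, overlap_fundamental_hz=cfg.base_hz
        ),
        "base": spectral.harmonic_range(cfg.base_hz, 48.0),
    }


def run_pipeline(
    cfg: AnalysisConfig,
    recordings: dict[str, RawRecording],
    groups: dict[str, str] | None = None,
    harmonic_sets: dict[str, HarmonicSet] | None = None,
    select_harmonics_from_data: bool = False,
) -> PipelineResult:
    """Execute all stages on a set of participant recordings.

    ``groups`` maps participant id -> between-group label (required when
    the config has a between factor). Harmonic sets default to the study's
    fixed ranges unless ``select_harmonics_from_data`` asks for the
    data-driven consecutive-significance rule.
    """
    montage = make_montage(cfg.montage)
    recipe = _recipe(cfg)
    if cfg.between_factor and groups is None:
        raise ValueError("config has a between factor but no groups given")

    per_participant_segments = {}
    for pid, rec in recordings.items():
        segs, _ = preprocess_recording(rec, cfg, montage)
        per_participant_segments[pid] = segs

    if harmonic_sets is None:
        harmonic_sets = default_harmonic_sets(cfg)
        if select_harmonics_from_data:
            harmonic_sets = _data_driven_harmonics(
                cfg, per_participant_segments, recipe
            )

    all_rows = []
    screen_rows = []
    for pid, segs in per_participant_segments.items():
        rows, s_rows, _ = analyze_participant(segs, cfg, harmonic_sets)
        for r in rows:
            r["participant"] = pid
            if groups:
                r["group"] = groups.get(pid, "")
        for r in s_rows:
            r["participant"] = pid
        all_rows.extend(rows)
        screen_rows.extend(s_rows)

    channel_table = pd.DataFrame(all_rows)
    screening_log = pd.DataFrame(
        screen_rows,
        columns=["participant", "epoch", "condition", "keep", "max_z",
                 "channel", "freq_hz"],
    )

    roi_rows = []
    if not channel_table.empty:
        roi_sets = {
            "oddball": quantify.ROI_PRESETS[cfg.roi_preset_face],
            "base": quantify.ROI_PRESETS[cfg.roi_preset_general],
        }
        for (pid, cond, resp), sub in channel_table.groupby(
            ["participant", "condition", "response"]
        ):
            amp_by_ch = dict(zip(sub["channel"], sub["amplitude_uv"]))
            z_by_ch = dict(zip(sub["channel"], sub["z"]))
            for roi in roi_sets[resp]:
                present = [c for c in roi.channels if c in amp_by_ch]
                if not present:
                    continue
                roi_rows.append({
                    "participant": pid, "condition": cond, "response": resp,
                    "roi": roi.name,
                    "amplitude_uv": float(np.mean([amp_by_ch[c] for c in present])),
                    "z": float(np.mean([z_by_ch[c] for c in present])),
                    "group": (groups or {}).get(pid, ""),
                })
    roi_table = pd.DataFrame(roi_rows)

    anova_tables = {}
    group_z = {}
    if not roi_table.empty:
        anova_tables = _run_stats(cfg, roi_table)
        for resp, sub in channel_table.groupby("response"):
            gz = sub.groupby(["condition", "channel"], observed=True)["z"] \
                    .mean().reset_index()
            group_z[resp] = gz

    return PipelineResult(
        config_hash=cfg.hash(),
        roi_table=roi_table,
        channel_table=channel_table,
        screening_log=screening_log,
        harmonic_sets=harmonic_sets,
        anova_tables=anova_tables,
        group_z=group_z,
    )


def _data_driven_harmonics(cfg, per_participant_segments, recipe):
    """Group-average all-channel Z spectra per condition, then apply the
    consecutive-significance harmonic selection."""
    epochs = []
    for segs in per_participant_segments.values():
        for seg in segs:
            epochs.append(spectral.epoch_exact_cycles(
                seg, cfg.epoch_offset_s, cfg.epoch_duration_s, cfg.oddball_hz
            ))
    z_by_cond = {}
    for cond, avg in spectral.average_epochs_by_condition(epochs).items():
        spec = spectral.amplitude_spectrum(avg).channel_average()
        _, z = spectral.correct_and_zscore(spec, recipe)
        z_by_cond[cond] = z
    return {
        "oddball": spectral.select_harmonics(
            z_by_cond, cfg.oddball_hz, cfg.base_hz,
            cfg.z_threshold, cfg.max_harmonic_hz,
        ),
        "base": spectral.select_harmonics(
            z_by_cond, cfg.base_hz, None, cfg.z_threshold, 48.0,
        ),
    }


def _split_condition(cond: str) -> dict[str, str]:
    """Map a condition label to factor levels: ``"new_intact"`` ->
    set=new, scrambling=intact; single-factor labels map to set."""
    parts = cond.split("_")
    if len(parts) == 2:
        return {"set": parts[0], "scrambling": parts[1]}
    return {"set": cond}


def _run_stats(cfg: AnalysisConfig, roi_table: pd.DataFrame):
    tables = {}
    for resp, sub in roi_table.groupby("response"):
        df = sub.copy()
        for fac, col in (("set", "set"), ("scrambling", "scrambling")):
            df[col] = [ _split_condition(c).get(fac, "") for c in df["condition"] ]
        within = [f for f in cfg.within_factors if f in ("set", "scrambling")
                  and df[f].nunique() > 1]
        if resp == "oddball" and df["roi"].nunique() > 1:
            within = within + ["roi"]
        else:
            df = df.groupby(
                ["participant", "set", "scrambling", "group"], observed=True
            )["amplitude_uv"].mean().reset_index()
        between = cfg.between_factor
        if between:
            df = df.rename(columns={"group": between})
        if not within:
            continue
        try:
            tables[resp] = stats.rm_anova(
                df, "amplitude_uv", within, "participant",
                between=between if between else None,
            )
        except ValueError as exc:
            log.warning("ANOVA skipped for %s: %s", resp, exc)
    return tables
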