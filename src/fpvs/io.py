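"""File formats: EDF read/write, BrainVision read, event tables, manifests.

EDF here is the plain 16-bit European Data Format; the writer emits a
single data record holding the whole recording (legal EDF, and exact for
round-tripping). Events travel in a TSV sidecar (``onset_s<TAB>label``)
next to the EDF file. BrainVision support is read-only
(.vhdr/.vmrk/.eeg, INT_16 or IEEE_FLOAT_32, multiplexed).
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path

import numpy as np

from .core import RawRecording

__all__ = [
    "write_edf",
    "read_edf",
    "read_brainvision",
    "write_events_tsv",
    "read_events_tsv",
    "write_manifest_json",
]

_DIG_MAX = 32767
_DIG_MIN = -32768


def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF (physical units μV) plus an events
    TSV sidecar at ``<path stem>_events.tsv``."""
    path = Path(path)
    data = recording.data
    n_sig = recording.n_channels
    n_samples = recording.n_samples
    duration = n_samples / recording.rate_hz

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_sig + 1)), 8),
        _pad("", 44),
        _pad("1", 8),                       # one data record
        _pad(f"{duration:.6g}", 8),
        _pad(str(n_sig), 4),
    ])
    fields = [
        [_pad(name, 16) for name in recording.channel_names],
        [_pad("EEG", 80)] * n_sig,
        [_pad("uV", 8)] * n_sig,
        [_pad(f"{v:.6g}", 8) for v in pmin],
        [_pad(f"{v:.6g}", 8) for v in pmax],
        [_pad(str(_DIG_MIN), 8)] * n_sig,
        [_pad(str(_DIG_MAX), 8)] * n_sig,
        [_pad("", 80)] * n_sig,
        [_pad(str(n_samples), 8)] * n_sig,
        [_pad("", 32)] * n_sig,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        for ch in range(n_sig):
            scale = (pmax[ch] - pmin[ch]) / (_DIG_MAX - _DIG_MIN)
            dig = np.round((data[ch] - pmin[ch]) / scale + _DIG_MIN)
            dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
            fh.write(dig.tobytes())
    if recording.events:
        write_events_tsv(recording.events, _events_path(path))
    return path


def _events_path(edf_path: Path) -> Path:
    return edf_path.with_name(edf_path.stem + "_events.tsv")


def read_edf(path: str | Path, rate_hz: float | None = None) -> RawRecording:
    """Read a 16-bit EDF file written by :func:`write_edf` (or any
    single-rate EDF). Events are loaded from the TSV sidecar if present.

    ``rate_hz`` overrides the rate inferred from the record duration (use
    when the duration field lost precision)."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    n_sig = int(raw[252:256].decode("ascii").strip())
    n_records = int(raw[236:244].decode("ascii").strip())
    rec_duration = float(raw[244:252].decode("ascii").strip())

    def field(offset: int, width: int) -> list[str]:
        base = 256 + offset * n_sig
        return [
            raw[base + i * width: base + (i + 1) * width].decode("ascii").strip()
            for i in range(n_sig)
        ]

    pos = 0
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    starts = []
    for w in widths:
        starts.append(pos)
        pos += w
    labels = field(starts[0], 16)
    pmin = np.array([float(v) for v in field(starts[3], 8)])
    pmax = np.array([float(v) for v in field(starts[4], 8)])
    dmin = np.array([float(v) for v in field(starts[5], 8)])
    dmax = np.array([float(v) for v in field(starts[6], 8)])
    spr = [int(v) for v in field(starts[8], 8)]

    header_bytes = 256 * (n_sig + 1)
    body = raw[header_bytes:]
    chans = [[] for _ in range(n_sig)]
    offset = 0
    for _ in range(n_records):
        for ch in range(n_sig):
            n = spr[ch]
            vals = np.frombuffer(body, dtype="<i2", count=n, offset=offset)
            offset += 2 * n
            chans[ch].append(vals)
    data = np.vstack([
        np.concatenate(parts).astype(float) for parts in chans
    ])
    for ch in range(n_sig):
        scale = (pmax[ch] - pmin[ch]) / (dmax[ch] - dmin[ch])
        data[ch] = (data[ch] - dmin[ch]) * scale + pmin[ch]

    if rate_hz is None:
        rate_hz = spr[0] / rec_duration
    events = []
    ev_path = _events_path(path)
    if ev_path.exists():
        events = read_events_tsv(ev_path)
    return RawRecording(data, rate_hz, labels, events)


def write_events_tsv(events: list[tuple[float, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("onset_s\tlabel\n")
        for t, label in events:
            fh.write(f"{t:.6f}\t{label}\n")
    return path


def read_events_tsv(path: str | Path) -> list[tuple[float, str]]:
    events = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("onset_s"):
            raise ValueError(f"{path}: expected 'onset_s\\tlabel' header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            t, label = line.split("\t", 1)
            events.append((float(t), label))
    return events


def write_manifest_json(manifest, path: str | Path) -> Path:
    """Serialize a GroundTruthManifest (numpy arrays as lists; the bulky
    clean-signal matrix is omitted)."""
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    payload = {
        "seed": manifest.seed,
        "component_amplitudes": manifest.component_amplitudes,
        "blink_times_s": manifest.blink_times_s,
        "spike_times_s": manifest.spike_times_s,
        "extra": {k: v for k, v in manifest.extra.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
    return path


def read_brainvision(vhdr_path: str | Path) -> RawRecording:
    """Read a BrainVision recording (.vhdr + .eeg + optional .vmrk)."""
    vhdr_path = Path(vhdr_path)
    parser = configparser.ConfigParser(interpolation=None, strict=False)
    text = vhdr_path.read_text()
    # strip the signature line, which is not INI syntax
    lines = [ln for ln in text.splitlines() if not ln.startswith("Brain Vision")]
    parser.read_string("\n".join(lines))

    common = parser["Common Infos"]
    data_file = vhdr_path.with_name(common["DataFile"])
    n_channels = int(common["NumberOfChannels"])
    rate_hz = 1e6 / float(common["SamplingInterval"])
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()

    binary = parser["Binary Infos"] if parser.has_section("Binary Infos") else {}
    fmt = binary.get("BinaryFormat", "INT_16").upper()
    dtype = {"INT_16": "<i2", "IEEE_FLOAT_32": "<f4"}.get(fmt)
    if dtype is None:
        raise ValueError(f"unsupported BinaryFormat: {fmt}")

    names = []
    resolutions = []
    ch_section = parser["Channel Infos"]
    for i in range(1, n_channels + 1):
        entry = ch_section[f"Ch{i}"]
        parts = entry.split(",")
        names.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    flat = np.fromfile(data_file, dtype=dtype).astype(float)
    n_samples = flat.size // n_channels
    flat = flat[: n_samples * n_channels]
    if orientation == "MULTIPLEXED":
        data = flat.reshape(n_samples, n_channels).T
    else:  # VECTORIZED
        data = flat.reshape(n_channels, n_samples)
    data = data * np.asarray(resolutions)[:, None]

    events: list[tuple[float, str]] = []
    if common.get("MarkerFile"):
        vmrk = vhdr_path.with_name(common["MarkerFile"])
        if vmrk.exists():
            mparser = configparser.ConfigParser(interpolation=None, strict=False)
            mlines = [ln for ln in vmrk.read_text().splitlines()
                      if not ln.startswith("Brain Vision")]
            mparser.read_string("\n".join(mlines))
            if mparser.has_section("Marker Infos"):
                for key, val in mparser["Marker Infos"].items():
                    parts = val.split(",")
                    if len(parts) < 3:
                        continue
                    mtype, desc, position = parts[0], parts[1], parts[2]
                    if mtype.lower() in ("stimulus", "s", "new segment") or desc:
                        events.append(((int(position) - 1) / rate_hz,
                                       desc or mtype))
    return RawRecording(data, rate_hz, names, events)
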