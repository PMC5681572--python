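"""Readers and writers for the package's artifact formats.

Events travel as TSV with the canonical header; continuous recordings as a
channel-major 32-bit float binary file plus a JSON sidecar; scenario and
run configurations as YAML. Times are milliseconds (written with
microsecond precision), depths mm (negative below pia).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .synthgen import ScenarioConfig
from .types import EVENT_COLUMNS, LaminarRecording, empty_events, validate_events


class ParseError(ValueError):
    pass


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.loc[:, list(EVENT_COLUMNS)].copy()
    out["time_ms"] = out["time_ms"].map(lambda t: f"{t:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event TSV; canonical sort applied. Errors name the line."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file without header") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: no events", stacklevel=2)
        return empty_events()
    times = pd.to_numeric(df["time_ms"], errors="coerce")
    bad = times.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ParseError(f"{path}: non-numeric time_ms at line {line}")
    df["time_ms"] = times
    layers = pd.to_numeric(df["layer"], errors="coerce")
    bad = layers.isna() | ~layers.isin([1, 2, 3, 4, 5, 6])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}: layer outside 1-6 at line {line}")
    df["layer"] = layers.astype(int)
    return validate_events(df)


def write_recording(recording: LaminarRecording, bin_path: str | Path, sidecar_path: str | Path) -> None:
    """Channel-major float32 binary plus JSON sidecar."""
    recording.samples.astype("<f4").tofile(bin_path)
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channel_order": [f"{h}:{l}" for h, l, _ in recording.channels],
        "depths_mm": [float(d) for _, _, d in recording.channels],
        "stimulus_onsets_ms": [float(t) for t in recording.stimulus_onsets_ms],
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_recording(bin_path: str | Path, sidecar_path: str | Path) -> LaminarRecording:
    try:
        sidecar = json.loads(Path(sidecar_path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{sidecar_path}: invalid JSON sidecar") from exc
    for fieldname in ("sampling_rate_hz", "channel_order", "depths_mm"):
        if fieldname not in sidecar:
            raise ParseError(f"{sidecar_path}: sidecar missing field {fieldname!r}")
    order = sidecar["channel_order"]
    depths = sidecar["depths_mm"]
    if len(order) != len(depths):
        raise ParseError(f"{sidecar_path}: channel_order and depths_mm lengths differ")
    raw = np.fromfile(bin_path, dtype="<f4")
    n_ch = len(order)
    if n_ch == 0 or raw.size % n_ch != 0:
        raise ParseError(
            f"{bin_path}: byte length not divisible by {n_ch} channels"
        )
    channels = []
    for label, depth in zip(order, depths):
        hemi, _, layer = label.partition(":")
        channels.append((hemi, int(layer), float(depth)))
    return LaminarRecording(
        samples=raw.reshape(n_ch, -1),
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        channels=channels,
        stimulus_onsets_ms=np.asarray(sidecar.get("stimulus_onsets_ms", []), dtype=float),
    )


def scenario_to_yaml(config: ScenarioConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["rates_hz"] = {h: list(map(float, r)) for h, r in d["rates_hz"].items()}
    d["evoked_window_ms"] = list(d["evoked_window_ms"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "rates_hz" in d:
        d["rates_hz"] = {h: tuple(r) for h, r in d["rates_hz"].items()}
    if "evoked_window_ms" in d:
        d["evoked_window_ms"] = tuple(d["evoked_window_ms"])
    if "participation" in d:
        d["participation"] = {int(k): float(v) for k, v in d["participation"].items()}
    return ScenarioConfig(**d)


def bundled_scenario_path(regime: str = "evoked") -> Path:
    """Path of the bundled paper-like scenario YAML."""
    name = {"evoked": "paper_like_evoked.yaml", "spontaneous": "paper_like_spontaneous.yaml"}[regime]
    return Path(__file__).parent / "data" / name


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration, for provenance."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True))
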