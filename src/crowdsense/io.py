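"""File I/O: event tables (CSV), results (JSON), configs (YAML), and
extended-XYZ trajectories.  All outputs are plain text and stable-ordered so
runs diff cleanly; every CLI invocation writes a manifest next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Any, Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .isotherm import REQUIRED_COLUMNS, validate_events
from .simulate import SimulationConfig

__all__ = [
    "read_event_table",
    "write_results",
    "parse_config",
    "dump_config",
    "write_manifest",
    "write_xyz",
    "read_xyz",
    "read_height_table",
]


def read_event_table(path) -> pd.DataFrame:
    """Read a per-event CSV table and validate its schema.

    Required header: sample_id, cell_id, bulk_conc_nM, anchor_fitc,
    probe_signal; optional: expression, treatment.  Malformed numeric rows
    are reported with their line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: file is empty") from None
    if len(df) == 0:
        raise DataError(f"{path}: table has a header but no rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("bulk_conc_nM", "anchor_fitc", "probe_signal"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
            raise DataError(f"{path}: non-numeric values in {col!r} at line(s) {lines}")
        df[col] = coerced
    return validate_events(df)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return str(obj)
    return obj


def write_results(obj: Any, path) -> None:
    """Write a result object as stable-ordered, diffable JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def parse_config(path) -> SimulationConfig:
    """Parse and validate a simulation YAML config (unknown keys rejected)."""
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    if raw is None:
        raise ConfigurationError(f"{path}: config file is empty")
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a YAML mapping")
    try:
        return SimulationConfig(**raw)
    except Exception as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def dump_config(config: SimulationConfig, path) -> None:
    """Emit a config echo that re-parses to an identical object."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


def write_manifest(
    out_dir,
    command: str,
    config: Optional[Dict[str, Any]] = None,
    seeds: Optional[Dict[str, int]] = None,
    inputs: Optional[Sequence[str]] = None,
    outputs: Optional[Sequence[str]] = None,
    wall_clock_s: Optional[float] = None,
) -> Path:
    """Write a run manifest making every CLI output re-derivable."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": _jsonable(config or {}),
        "seeds": seeds or {},
        "package_version": __version__,
        "inputs": [str(p) for p in (inputs or [])],
        "outputs": [str(p) for p in (outputs or [])],
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "wall_clock_s": wall_clock_s,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_xyz(frames: np.ndarray, box_xy_nm: Tuple[float, float], path,
              comment_extra: str = "") -> None:
    """Write frames (n_frames, n_beads, 3) as extended-XYZ text (nm)."""
    frames = np.asarray(frames)
    with open(path, "w") as fh:
        for fi, frame in enumerate(frames):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(
                f'frame={fi} box_xy_nm="{box_xy_nm[0]} {box_xy_nm[1]}" '
                f"units=nm {comment_extra}".rstrip() + "\n"
            )
            for x, y, z in frame:
                fh.write(f"B {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Read an extended-XYZ trajectory back into (frames, box)."""
    frames = []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError:
            raise DataError(f"{path}: expected an atom count at line {i + 1}") from None
        comment = lines[i + 1]
        if 'box_xy_nm="' in comment:
            part = comment.split('box_xy_nm="')[1].split('"')[0].split()
            box = (float(part[0]), float(part[1]))
        rows = []
        for j in range(n):
            fields = lines[i + 2 + j].split()
            rows.append([float(fields[1]), float(fields[2]), float(fields[3])])
        frames.append(rows)
        i += 2 + n
    if not frames:
        raise DataError(f"{path}: no frames found")
    if box is None:
        raise DataError(f"{path}: no box_xy_nm metadata in comment lines")
    return np.asarray(frames, dtype=float), box


def read_height_table(path) -> pd.DataFrame:
    """Read a CSOP-style height CSV (cell_id, h_measured_nm, label, qc_flags)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: file is empty") from None
    if "h_measured_nm" not in df.columns:
        raise DataError(f"{path}: missing required column 'h_measured_nm'")
    if len(df) == 0:
        raise DataError(f"{path}: table has a header but no rows")
    return df
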