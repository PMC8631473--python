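"""File formats and run artifacts.

Stacks are single-channel multi-page TIFF (16-bit unsigned counts);
track tables and per-event results are CSV; calibration output and the
run manifest are JSON; configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationResult
from .pore_metrics import EventSummary, summaries_to_frame
from .simulate import ImageStack, SimulationConfig

__all__ = [
    "read_stack",
    "write_stack",
    "read_tracks",
    "write_results",
    "load_config",
    "config_hash",
]

TRACK_COLUMNS = ["event_id", "frame", "x_px", "y_px", "dock_frame", "fusion_frame"]


def read_stack(
    path: str | Path,
    pixel_size_nm: float = 265.0,
    frame_interval_s: float = 0.0183,
) -> ImageStack:
    """Load a single-channel multi-page TIFF as an image stack.

    Raises a format error naming the defect for multi-channel (RGB or
    multi-sample) or non-3D files, and the usual I/O error for a missing
    path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        axes = tif.series[0].axes
        if "S" in axes or "C" in axes:
            raise ValueError(
                f"multi-channel TIFF {path}: axes {axes!r}, expected a "
                "single-channel grayscale stack"
            )
        data = tif.series[0].asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"malformed TIFF {path}: expected single-channel pages, got "
            f"shape {data.shape}"
        )
    return ImageStack(
        data=data.astype(float),
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
        truth=pd.DataFrame(),
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as 16-bit multi-page TIFF (counts clipped to range)."""
    data = np.clip(np.round(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a centroid track table (event_id, frame, x_px, y_px, dock_frame,
    fusion_frame)."""
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table {path} missing columns: {sorted(missing)}")
    return df


def track_array(tracks: pd.DataFrame, event_id: int, n_frames: int) -> np.ndarray:
    """Per-stack-frame (x, y) array for one event, NaN outside the track."""
    sub = tracks[tracks["event_id"] == event_id]
    arr = np.full((n_frames, 2), np.nan)
    f = sub["frame"].to_numpy(dtype=int)
    arr[f, 0] = sub["x_px"].to_numpy(dtype=float)
    arr[f, 1] = sub["y_px"].to_numpy(dtype=float)
    return arr


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict | SimulationConfig) -> str:
    """Stable hash of a configuration mapping (changes iff a field does)."""
    if isinstance(config, SimulationConfig):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    events: Sequence[EventSummary],
    out_dir: str | Path,
    calibration: CalibrationResult | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write the per-event CSV, calibration JSON and run manifest.

    Returns the manifest dict.  The manifest records the configuration
    hash, seed, package version and accepted/rejected counts by reason.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = summaries_to_frame(events)
    df.to_csv(out_dir / "events.csv", index=False)

    if calibration is not None:
        with open(out_dir / "calibration.json", "w") as fh:
            json.dump(calibration.to_dict(), fh, indent=2)
        for name, binned in calibration.binned.items():
            binned.to_csv(out_dir / f"binned_{name}.csv", index=False)

    from . import __version__

    counts: dict[str, int] = {"accepted": int((~df["rejected"]).sum())}
    for reason, k in df.loc[df["rejected"], "reason"].value_counts().items():
        counts[str(reason)] = int(k)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "n_events": int(len(df)),
        "counts": counts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
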