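"""Shared readers and writers: TIFF movies with JSON calibration sidecars,
and versioned CSV tables for every pipeline stage.

Conventions: dimension order TZYX per channel; 0-based frame indices in
files; physical columns suffixed ``_um`` / ``_s``; missing values are empty
fields in CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

SCHEMA_VERSION = 1
SIDECAR_NAME = "movie.json"

SCHEMAS: dict[str, list[str]] = {
    "tracks": ["cell_id", "frame", "t_s", "x_um", "y_um", "z_um", "mitosis_flag", "excluded"],
    "traces": ["cell_id", "frame", "t_s", "F", "roi_diameter_um", "overlap_flag"],
    "dff": ["cell_id", "frame", "t_s", "dff", "F0"],
    "peaks": ["cell_id", "apex_frame", "apex_time_s", "apex_dff", "prominence",
              "onset_time_s", "time_to_peak_s"],
    "metrics": ["cell_id", "n_peaks", "frequency_per_min", "mean_dff",
                "observed_duration_s", "oscillating"],
    "synchrony": ["cell_a", "cell_b", "n_rises_a", "n_rises_b",
                  "pct_synchronous_a", "pct_synchronous_b", "window_s"],
    "regions": ["cell_id", "region", "left_x_um", "right_x_um", "nucleus_x_um"],
    "boundary_counts": ["boundary_x_um", "n_oscillating", "category"],
    "spikes": ["cell_id", "spike_time_s", "amplitude_dff", "rise_time_s", "decay_time_s"],
    "annotations": ["cell_id", "role", "side", "budding", "following_tip",
                    "boundary_index", "x_um", "y_um", "z_um"],
    "boundaries": ["x_um"],
}


@dataclass
class MovieHandle:
    """An in-memory two-channel 4D movie with physical calibration."""

    channels: dict[str, np.ndarray]  # name -> (T, Z, Y, X)
    xy_pixel_um: float
    z_step_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("movie must carry at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        for name, shape in shapes.items():
            if len(shape) != 4 or any(s <= 0 for s in shape):
                raise ValueError(f"channel {name!r} is not a positive (T,Z,Y,X) array: {shape}")
        first = next(iter(shapes.values()))
        for name, shape in shapes.items():
            if shape != first:
                raise ValueError(
                    f"channel dims differ: {shapes}"
                )
        for label, v in (
            ("xy_pixel_um", self.xy_pixel_um),
            ("z_step_um", self.z_step_um),
            ("frame_interval_s", self.frame_interval_s),
        ):
            if not (v > 0):
                raise ValueError(f"{label} must be > 0, got {v}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return tuple(next(iter(self.channels.values())).shape[1:])

    @property
    def voxel_size_zyx_um(self) -> tuple[float, float, float]:
        return (self.z_step_um, self.xy_pixel_um, self.xy_pixel_um)

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def write_movie(movie: MovieHandle, directory) -> Path:
    """Write one multi-dimensional TIFF per channel plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in movie.channels.items():
        tifffile.imwrite(directory / f"{name}.tif", np.asarray(arr, dtype=np.float32))
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "dimension_order": "TZYX",
        "channels": sorted(movie.channels),
        "xy_pixel_um": movie.xy_pixel_um,
        "z_step_um": movie.z_step_um,
        "frame_interval_s": movie.frame_interval_s,
    }
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return directory


def read_movie(directory) -> MovieHandle:
    """Read a TIFF movie directory written by :func:`write_movie`.

    Validates the calibration sidecar and that all channels share dims.
    """
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"calibration sidecar {SIDECAR_NAME} missing in {directory}"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("xy_pixel_um", "z_step_um", "frame_interval_s", "channels"):
        if key not in meta:
            raise ValueError(f"sidecar missing required key {key!r}")
    channels = {}
    for name in meta["channels"]:
        path = directory / f"{name}.tif"
        if not path.exists():
            raise FileNotFoundError(f"channel file missing: {path}")
        channels[name] = tifffile.imread(path)
    return MovieHandle(
        channels=channels,
        xy_pixel_um=float(meta["xy_pixel_um"]),
        z_step_um=float(meta["z_step_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
    )


def write_table(df: pd.DataFrame, path, schema: str) -> Path:
    """Write a stage table as CSV with a versioned schema header line.

    Columns must match the stage schema exactly (order is normalised);
    missing values become empty fields.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    extra = [c for c in df.columns if c not in cols]
    if missing or extra:
        raise ValueError(
            f"schema {schema!r} violation: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# caosc-table schema={schema} version={SCHEMA_VERSION}\n")
        df[cols].to_csv(fh, index=False)
    return path


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a stage CSV; if ``schema`` is given, validate its columns."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if schema is not None:
        cols = SCHEMAS[schema]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"table at {path} missing columns {missing}")
        df = df[cols]
    return df
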