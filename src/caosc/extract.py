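"""Spherical-ROI fluorescence extraction.

Each tracked cell gets one spherical region of interest, sized to cover the
nucleus plus part of the cytoplasm without touching neighbouring cells'
spheres, and the indicator signal F(t) is the brightest voxel inside the
sphere at each time point.  Because a Ca2+ spike fills the whole cytoplasm,
the single brightest voxel is a faithful readout and is insensitive to the
exact ROI size.

Sphere membership is decided on voxel centres in physical micrometres, so the
anisotropy between the lateral pixel pitch and the z-step is honoured: a voxel
one z-plane (4 µm) away and one eight-pixels (4 µm) away laterally are treated
identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiSpec", "FluorescenceTrace", "fit_roi_diameter", "extract_trace"]

#: allowed ROI diameter range (µm): slightly larger than a nucleus, never
#: reaching into neighbouring cells.
DEFAULT_DIAMETER_RANGE_UM = (4.0, 11.0)
DIAMETER_GRID_UM = 0.5


@dataclass
class FluorescenceTrace:
    """Raw per-cell fluorescence F(t) in arbitrary camera units.

    ``F`` is NaN at frames where the trajectory has a gap or the ROI fell
    outside the imaged volume; downstream stages skip, never interpolate,
    missing samples.
    """

    cell_id: object
    t_s: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t_s.shape != self.F.shape:
            raise ValueError("t_s and F must have the same length")
        finite = self.F[np.isfinite(self.F)]
        if finite.size and finite.min() < 0:
            raise ValueError("fluorescence must be non-negative")

    def __len__(self) -> int:
        return len(self.F)

    @property
    def frame_interval_s(self) -> float:
        if len(self.t_s) < 2:
            raise ValueError("trace too short to define a frame interval")
        return float(self.t_s[1] - self.t_s[0])


@dataclass
class RoiSpec:
    """One cell's spherical ROI: a single diameter, centred on the nucleus
    centroid at every frame."""

    cell_id: object
    diameter_um: float
    overlap_flag: bool = False

    def __post_init__(self) -> None:
        lo, hi = DEFAULT_DIAMETER_RANGE_UM
        if not (lo <= self.diameter_um <= hi):
            raise ValueError(
                f"ROI diameter {self.diameter_um} outside [{lo}, {hi}] µm"
            )

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


def _pairwise_min_distance(pos_a: np.ndarray, pos_b: np.ndarray) -> float:
    """Minimum frame-wise distance between two (T, 3) position arrays,
    ignoring frames where either cell is absent (NaN)."""
    d = pos_a - pos_b
    dist = np.sqrt(np.nansum(d * d, axis=1))
    valid = np.isfinite(d).all(axis=1)
    if not valid.any():
        return np.inf
    return float(dist[valid].min())


def fit_roi_diameter(
    trajectory,
    all_trajectories,
    n_frames: int,
    d_range_um: tuple[float, float] = DEFAULT_DIAMETER_RANGE_UM,
    grid_um: float = DIAMETER_GRID_UM,
) -> RoiSpec:
    """Choose the largest admissible ROI diameter for one cell.

    The sphere must clear every neighbouring cell's sphere at every frame
    (assuming neighbours are sized by the same rule, two spheres just touch
    when the centre distance equals the diameter).  The diameter is searched
    on a ``grid_um`` grid within ``d_range_um`` and held constant over time.
    If even the minimum diameter cannot clear a neighbour the minimum is used
    and ``overlap_flag`` is set.
    """
    d_min, d_max = d_range_um
    own = trajectory.positions_full(n_frames)
    min_dist = np.inf
    for other in all_trajectories:
        if other is trajectory or other.cell_id == trajectory.cell_id:
            continue
        min_dist = min(min_dist, _pairwise_min_distance(own, other.positions_full(n_frames)))

    grid = np.arange(d_min, d_max + 0.5 * grid_um, grid_um)
    feasible = grid[grid <= min_dist + 1e-9]
    if feasible.size == 0:
        return RoiSpec(trajectory.cell_id, d_min, overlap_flag=True)
    return RoiSpec(trajectory.cell_id, float(feasible[-1]), overlap_flag=False)


def max_in_sphere(
    volume: np.ndarray,
    center_um: np.ndarray,
    radius_um: float,
    voxel_size_zyx_um: tuple[float, float, float],
) -> float:
    """Maximum voxel value whose centre lies within ``radius_um`` of
    ``center_um`` (x, y, z µm).  NaN if no voxel centre falls inside the
    sphere within the volume."""
    cx, cy, cz = (float(c) for c in center_um)
    sz, sy, sx = voxel_size_zyx_um
    nz, ny, nx = volume.shape

    def _rng(c, step, n):
        lo = max(0, int(np.ceil((c - radius_um) / step)))
        hi = min(n - 1, int(np.floor((c + radius_um) / step)))
        return lo, hi

    zlo, zhi = _rng(cz, sz, nz)
    ylo, yhi = _rng(cy, sy, ny)
    xlo, xhi = _rng(cx, sx, nx)
    if zlo > zhi or ylo > yhi or xlo > xhi:
        return np.nan

    zz = (np.arange(zlo, zhi + 1) * sz - cz) ** 2
    yy = (np.arange(ylo, yhi + 1) * sy - cy) ** 2
    xx = (np.arange(xlo, xhi + 1) * sx - cx) ** 2
    d2 = (zz[:, None, None] + yy[None, :, None]) + xx[None, None, :]
    mask = d2 <= radius_um * radius_um
    if not mask.any():
        return np.nan
    sub = volume[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1]
    return float(sub[mask].max())


def extract_trace(movie, roi: RoiSpec, trajectory, channel: str = "indicator") -> FluorescenceTrace:
    """Extract F(t) = brightest indicator voxel inside the cell's ROI.

    Frames where the trajectory has a gap are NaN.  A frame where the sphere
    contains no voxel centre (ROI outside the volume) is NaN with a warning.
    """
    vols = movie.channels[channel]
    n_frames = vols.shape[0]
    centers = trajectory.positions_full(n_frames)
    voxel = movie.voxel_size_zyx_um
    F = np.full(n_frames, np.nan)
    outside = 0
    for t in range(n_frames):
        c = centers[t]
        if not np.isfinite(c).all():
            continue
        val = max_in_sphere(vols[t], c, roi.radius_um, voxel)
        if np.isnan(val):
            outside += 1
        F[t] = val
    if outside:
        warnings.warn(
            f"cell {roi.cell_id}: ROI contained no voxel at {outside} frame(s); "
            "marked missing",
            stacklevel=2,
        )
    t_s = np.arange(n_frames) * movie.frame_interval_s
    return FluorescenceTrace(cell_id=roi.cell_id, t_s=t_s, F=F)
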