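"""Physical calibration of a light-sheet acquisition.

All physical quantities are carried in micrometres and seconds throughout the
package; voxel arrays are ordered (Z, Y, X) and movies (T, Z, Y, X).  The
coordinate of the voxel with index (k, j, i) is (x, y, z) =
(i * xy_pixel_um, j * xy_pixel_um, k * z_step_um), i.e. the origin sits at the
centre of the corner voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AcquisitionConfig:
    """Calibration of one two-channel volumetric time series.

    Defaults mirror a typical in-vivo GCaMP light-sheet session: one volume
    every 5 s, 4 µm z-planes, recordings of 1000-2000 s.
    """

    frame_interval_s: float = 5.0
    z_step_um: float = 4.0
    xy_pixel_um: float = 0.5
    duration_s: float = 1000.0
    volume_shape: tuple[int, int, int] = (16, 64, 128)  # (Z, Y, X) voxels
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.z_step_um <= 0 or self.xy_pixel_um <= 0:
            raise ValueError("voxel sizes must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.n_frames < 2:
            raise ValueError(
                f"duration_s={self.duration_s} at frame_interval_s="
                f"{self.frame_interval_s} yields fewer than 2 frames"
            )
        if len(self.volume_shape) != 3 or any(int(s) <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be three positive (Z, Y, X) extents")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def voxel_size_zyx_um(self) -> tuple[float, float, float]:
        return (self.z_step_um, self.xy_pixel_um, self.xy_pixel_um)

    @property
    def volume_extent_um(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extent spanned by voxel centres."""
        nz, ny, nx = self.volume_shape
        return (
            (nz - 1) * self.z_step_um,
            (ny - 1) * self.xy_pixel_um,
            (nx - 1) * self.xy_pixel_um,
        )
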