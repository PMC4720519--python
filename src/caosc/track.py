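"""Nucleus detection and frame-to-frame linking.

Replaces the interactive tracking step of the original workflow: nuclei are
detected per frame in the nuclear channel (Gaussian smoothing, thresholding,
connected components with intensity-weighted sub-voxel centroids) and linked
across frames by optimal bipartite assignment on Euclidean distance in
physical micrometres, gated by a maximum displacement, with gap closing.
Cells that divide during the recording never show a Ca2+ rise in M phase, so
divisions are flagged and the involved trajectories excluded from
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Detection",
    "NucleusTrajectory",
    "detect_nuclei",
    "link_tracks",
    "flag_mitosis",
    "evaluate_tracking",
]

_GATE_COST = 1e12


@dataclass
class Detection:
    """One nucleus candidate in one frame; centroid in (x, y, z) µm."""

    frame: int
    centroid_um: np.ndarray
    intensity: float
    radius_um: float = 0.0

    def __post_init__(self) -> None:
        self.centroid_um = np.asarray(self.centroid_um, dtype=float)
        if self.centroid_um.shape != (3,):
            raise ValueError("centroid_um must be (x, y, z)")


@dataclass
class NucleusTrajectory:
    """A linked nucleus track; gaps are allowed (frames need not be
    contiguous) but frame indices are strictly increasing."""

    cell_id: int
    frames: np.ndarray
    centroids_um: np.ndarray  # (n, 3) x/y/z µm
    detection_indices: list = field(default_factory=list)
    mitosis_flag: bool = False
    excluded: bool = False
    role_label: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.centroids_um = np.asarray(self.centroids_um, dtype=float)
        if len(self.frames) != len(self.centroids_um):
            raise ValueError("frames and centroids must align")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.mitosis_flag:
            self.excluded = True

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    def positions_full(self, n_frames: int) -> np.ndarray:
        """(n_frames, 3) positions with NaN at frames without a detection."""
        out = np.full((n_frames, 3), np.nan)
        out[self.frames] = self.centroids_um
        return out


def detect_nuclei(
    volume: np.ndarray,
    voxel_size_zyx_um: tuple[float, float, float],
    smooth_sigma_um: float = 2.0,
    threshold: float = 50.0,
    min_voxels: int = 2,
    frame: int = 0,
) -> list[Detection]:
    """Detect nuclei in one (Z, Y, X) volume.

    The volume is smoothed with a Gaussian of physical width
    ``smooth_sigma_um`` (converted per axis to voxels, honouring anisotropy),
    thresholded, and each connected component above ``min_voxels`` becomes
    one detection with an intensity-weighted sub-voxel centroid.
    """
    if voxel_size_zyx_um is None or any(not (s > 0) for s in voxel_size_zyx_um):
        raise ValueError("volume physical calibration missing or invalid")
    vol = np.asarray(volume, dtype=float)
    sigma_vox = [smooth_sigma_um / s for s in voxel_size_zyx_um]
    sm = ndi.gaussian_filter(vol, sigma=sigma_vox)
    mask = sm > threshold
    labels, n_labels = ndi.label(mask)
    detections: list[Detection] = []
    if n_labels == 0:
        return detections
    sz, sy, sx = voxel_size_zyx_um
    voxel_volume = sz * sy * sx
    for sl, lab in zip(ndi.find_objects(labels), range(1, n_labels + 1)):
        region = labels[sl] == lab
        n_vox = int(region.sum())
        if n_vox < min_voxels:
            continue
        w = np.where(region, sm[sl] - threshold, 0.0)
        total = w.sum()
        zz, yy, xx = np.nonzero(region)
        wz = w[zz, yy, xx]
        z_c = (zz + sl[0].start) @ wz / total
        y_c = (yy + sl[1].start) @ wz / total
        x_c = (xx + sl[2].start) @ wz / total
        radius = (3.0 * n_vox * voxel_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        detections.append(
            Detection(
                frame=frame,
                centroid_um=np.array([x_c * sx, y_c * sy, z_c * sz]),
                intensity=float(vol[sl][region].max()),
                radius_um=float(radius),
            )
        )
    # stable output order: by (z, y, x) centroid
    detections.sort(key=lambda d: (d.centroid_um[2], d.centroid_um[1], d.centroid_um[0]))
    return detections


def detect_movie(movie, channel: str = "nuclear", **kwargs) -> list[list[Detection]]:
    """Run :func:`detect_nuclei` on every frame of a movie."""
    vols = movie.channels[channel]
    return [
        detect_nuclei(vols[t], movie.voxel_size_zyx_um, frame=t, **kwargs)
        for t in range(vols.shape[0])
    ]


class _OpenTrack:
    __slots__ = ("frames", "centroids", "det_indices")

    def __init__(self, frame: int, det: Detection, det_idx: int):
        self.frames = [frame]
        self.centroids = [det.centroid_um]
        self.det_indices = [(frame, det_idx)]

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def last_centroid(self) -> np.ndarray:
        return self.centroids[-1]

    def extend(self, frame: int, det: Detection, det_idx: int) -> None:
        self.frames.append(frame)
        self.centroids.append(det.centroid_um)
        self.det_indices.append((frame, det_idx))


def link_tracks(
    detections_by_frame: list[list[Detection]],
    max_disp_um: float = 6.0,
    gap_max: int = 0,
    min_track_len: int = 1,
) -> list[NucleusTrajectory]:
    """Link per-frame detections into trajectories.

    Per frame pair the total gated displacement is minimised by optimal
    assignment (scipy's Hungarian solver); a link is admissible when the
    displacement is at most ``max_disp_um`` per elapsed frame interval, so a
    track may bridge up to ``gap_max`` missed frames.  Unmatched detections
    start new tracks; each detection belongs to at most one trajectory.
    Tracks shorter than ``min_track_len`` detections are dropped.
    """
    active: list[_OpenTrack] = []
    finished: list[_OpenTrack] = []
    for t, dets in enumerate(detections_by_frame):
        candidates = [tr for tr in active if t - tr.last_frame <= gap_max + 1]
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if candidates and dets:
            cost = np.full((len(candidates), len(dets)), _GATE_COST)
            for i, tr in enumerate(candidates):
                elapsed = t - tr.last_frame
                gate = max_disp_um * elapsed
                for j, det in enumerate(dets):
                    d = float(np.linalg.norm(tr.last_centroid - det.centroid_um))
                    if d <= gate:
                        cost[i, j] = d
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < _GATE_COST:
                    candidates[i].extend(t, dets[j], j)
                    matched_tracks.add(id(candidates[i]))
                    matched_dets.add(j)
        for j, det in enumerate(dets):
            if j not in matched_dets:
                active.append(_OpenTrack(t, det, j))
        still_active = []
        for tr in active:
            if t - tr.last_frame > gap_max + 1:
                finished.append(tr)
            else:
                still_active.append(tr)
        active = still_active
    finished.extend(active)
    finished.sort(key=lambda tr: (tr.frames[0], tuple(tr.centroids[0])))
    trajectories = [
        NucleusTrajectory(
            cell_id=i,
            frames=np.array(tr.frames),
            centroids_um=np.array(tr.centroids),
            detection_indices=tr.det_indices,
        )
        for i, tr in enumerate(finished)
        if len(tr.frames) >= min_track_len
    ]
    # re-number after the length filter
    for i, tr in enumerate(trajectories):
        tr.cell_id = i
    used: set[tuple[int, int]] = set()
    for tr in trajectories:
        for key in tr.detection_indices:
            if key in used:
                raise AssertionError("detection assigned to two trajectories")
            used.add(key)
    return trajectories


def flag_mitosis(
    trajectories: list[NucleusTrajectory],
    detections_by_frame: list[list[Detection]],
    split_radius_um: float = 6.0,
) -> list[NucleusTrajectory]:
    """Flag divisions: a frame where exactly one detection sits within
    ``split_radius_um`` of a trajectory and two or more do one frame later
    marks a division; the trajectory and any track starting at that next
    frame from those detections are flagged and excluded.

    Works on raw detections, so a division whose daughters are too
    short-lived to form tracks (e.g. at the movie's final frame) still flags
    the parent.
    """
    n_frames = len(detections_by_frame)
    owner: dict[tuple[int, int], NucleusTrajectory] = {}
    for tr in trajectories:
        for key in tr.detection_indices:
            owner[key] = tr

    def _near(frame: int, pos: np.ndarray) -> list[int]:
        return [
            j
            for j, det in enumerate(detections_by_frame[frame])
            if np.linalg.norm(det.centroid_um - pos) <= split_radius_um
        ]

    for tr in trajectories:
        for frame, pos in zip(tr.frames, tr.centroids_um):
            if frame + 1 >= n_frames:
                continue
            if len(_near(int(frame), pos)) != 1:
                continue
            near_next = _near(int(frame) + 1, pos)
            if len(near_next) < 2:
                continue
            tr.mitosis_flag = True
            tr.excluded = True
            for j in near_next:
                daughter = owner.get((int(frame) + 1, j))
                if daughter is not None and daughter.first_frame == int(frame) + 1:
                    daughter.mitosis_flag = True
                    daughter.excluded = True
    return trajectories


def annotate_tracks(
    trajectories: list[NucleusTrajectory],
    annotations,
    max_match_um: float = 5.0,
) -> dict[int, dict]:
    """Match trajectories to an annotation table by start position.

    ``annotations`` is a DataFrame with columns cell_id, role, side, budding,
    following_tip, boundary_index, x_um, y_um, z_um (start-of-recording
    nucleus positions).  Returns cell_id -> annotation row dict for matched
    trajectories and sets ``role_label``.
    """
    ann_pos = annotations[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    out: dict[int, dict] = {}
    for tr in trajectories:
        start = tr.centroids_um[0]
        d = np.linalg.norm(ann_pos - start, axis=1)
        k = int(np.argmin(d)) if len(d) else -1
        if k >= 0 and d[k] <= max_match_um:
            row = annotations.iloc[k].to_dict()
            tr.role_label = row["role"]
            out[tr.cell_id] = row
    return out


def evaluate_tracking(
    trajectories: list[NucleusTrajectory],
    gt_positions: dict,
    n_frames: int,
    match_radius_um: float = 4.0,
) -> dict:
    """Score linking against ground truth.

    For every ground-truth cell and consecutive frame pair where the cell is
    present, the link is correct when one single trajectory is the nearest
    (within ``match_radius_um``) to the ground-truth position at both frames.
    Returns the link recall and counts.
    """
    full = [tr.positions_full(n_frames) for tr in trajectories]
    n_links = 0
    n_correct = 0
    for frames, pos in gt_positions.values():
        frame_to_pos = dict(zip(frames.tolist(), pos))
        for f in frames.tolist():
            if f + 1 not in frame_to_pos:
                continue
            n_links += 1
            match = []
            for f_i, p_gt in ((f, frame_to_pos[f]), (f + 1, frame_to_pos[f + 1])):
                best, best_d = None, match_radius_um
                for k, tr_pos in enumerate(full):
                    p = tr_pos[f_i]
                    if not np.isfinite(p).all():
                        continue
                    d = float(np.linalg.norm(p - p_gt))
                    if d <= best_d:
                        best, best_d = k, d
                match.append(best)
            if match[0] is not None and match[0] == match[1]:
                n_correct += 1
    recall = n_correct / n_links if n_links else np.nan
    return {"n_links": n_links, "n_correct": n_correct, "link_recall": recall}
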