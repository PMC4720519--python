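"""Detection, linking and mitosis flagging against brute-force oracles and
ground-truth scenes."""

import numpy as np
import pytest

from caosc.config import AcquisitionConfig
from caosc import synthgen as sg, track

from oracles import brute_min_cost_assignment

VOXEL = (4.0, 1.0, 1.0)  # (z, y, x) µm


def gaussian_blob_volume(shape, centers_um, amplitude=150.0, sigma_um=2.0,
                         voxel=VOXEL, background=0.0):
    nz, ny, nx = shape
    sz, sy, sx = voxel
    zz = np.arange(nz)[:, None, None] * sz
    yy = np.arange(ny)[None, :, None] * sy
    xx = np.arange(nx)[None, None, :] * sx
    vol = np.full(shape, background)
    for (x, y, z) in centers_um:
        d2 = (zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2
        vol = np.maximum(vol, amplitude * np.exp(-0.5 * d2 / sigma_um**2))
    return vol


class TestDetectNuclei:
    def test_single_blob_centroid_matches_center_of_mass(self):
        """One noise-free Gaussian blob -> exactly one detection whose
        centroid lies within one voxel of the brute-force argmax /
        centre-of-mass."""
        center = (10.3, 7.6, 8.9)
        vol = gaussian_blob_volume((6, 16, 24), [center])
        dets = track.detect_nuclei(vol, VOXEL, threshold=30.0)
        assert len(dets) == 1
        # brute-force oracle: intensity argmax and centre of mass
        k, j, i = np.unravel_index(np.argmax(vol), vol.shape)
        argmax_um = np.array([i * VOXEL[2], j * VOXEL[1], k * VOXEL[0]])
        w = np.clip(vol - 30.0, 0, None)
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in vol.shape], indexing="ij")
        com_um = np.array([
            (xx * w).sum() / w.sum() * VOXEL[2],
            (yy * w).sum() / w.sum() * VOXEL[1],
            (zz * w).sum() / w.sum() * VOXEL[0],
        ])
        voxel_diag = np.array([VOXEL[2], VOXEL[1], VOXEL[0]])
        assert np.all(np.abs(dets[0].centroid_um - com_um) <= voxel_diag)
        assert np.all(np.abs(dets[0].centroid_um - argmax_um) <= voxel_diag)
        assert np.linalg.norm(dets[0].centroid_um - np.array(center)) < 1.0

    def test_empty_volume_no_detections(self):
        assert track.detect_nuclei(np.zeros((6, 16, 24)), VOXEL) == []

    def test_two_separated_blobs_two_detections(self):
        centers = [(6.0, 8.0, 8.0), (16.0, 8.0, 8.0)]  # 10 µm apart in x
        vol = gaussian_blob_volume((6, 16, 24), centers)
        dets = track.detect_nuclei(vol, VOXEL, threshold=30.0)
        assert len(dets) == 2
        got_x = sorted(d.centroid_um[0] for d in dets)
        assert got_x == pytest.approx([6.0, 16.0], abs=0.5)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            track.detect_nuclei(np.zeros((4, 4, 4)), (0.0, 1.0, 1.0))


def _dets(frame, positions):
    return [
        track.Detection(frame=frame, centroid_um=np.asarray(p, dtype=float),
                        intensity=100.0)
        for p in positions
    ]


class TestLinkTracks:
    def test_two_static_nuclei(self):
        frames = [_dets(t, [(0.0, 0.0, 0.0), (20.0, 0.0, 0.0)]) for t in range(10)]
        trajs = track.link_tracks(frames, max_disp_um=6.0)
        assert len(trajs) == 2
        for tr in trajs:
            assert len(tr) == 10
            assert np.allclose(np.diff(tr.centroids_um, axis=0), 0.0)

    def test_linking_equals_min_total_displacement_assignment(self):
        """Randomised frame pairs with <=4 detections: the chosen links
        minimise total gated displacement (exhaustive permutation oracle)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 5)
            a = rng.uniform(0, 40, size=(n, 3))
            b = a[rng.permutation(n)] + rng.uniform(-2, 2, size=(n, 3))
            frames = [_dets(0, a), _dets(1, b)]
            trajs = track.link_tracks(frames, max_disp_um=50.0)
            assert len(trajs) == n
            total = 0.0
            for tr in trajs:
                assert len(tr) == 2
                total += np.linalg.norm(tr.centroids_um[1] - tr.centroids_um[0])
            cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            best, _ = brute_min_cost_assignment(cost)
            assert total == pytest.approx(best, abs=1e-9)

    def test_swap_resolved_by_assignment(self):
        # two nuclei approaching and swapping lanes with small steps
        pos_a = [(0.0 + t, 0.0, 0.0) for t in range(10)]
        pos_b = [(9.0 - t, 3.0, 0.0) for t in range(10)]
        frames = [_dets(t, [pa, pb]) for t, (pa, pb) in enumerate(zip(pos_a, pos_b))]
        trajs = track.link_tracks(frames, max_disp_um=2.5)
        assert len(trajs) == 2
        # each trajectory keeps its own y-lane (min-displacement solution)
        for tr in trajs:
            assert np.ptp(tr.centroids_um[:, 1]) == pytest.approx(0.0)

    def test_gap_closing_bridges_missing_frames(self):
        frames = []
        for t in range(10):
            if t in (4, 5):
                frames.append([])
            else:
                frames.append(_dets(t, [(float(t), 0.0, 0.0)]))
        trajs = track.link_tracks(frames, max_disp_um=2.0, gap_max=2)
        assert len(trajs) == 1
        assert trajs[0].first_frame == 0 and trajs[0].last_frame == 9

    def test_no_detection_shared_between_tracks(self):
        rng = np.random.default_rng(3)
        frames = [_dets(t, rng.uniform(0, 30, size=(4, 3))) for t in range(6)]
        trajs = track.link_tracks(frames, max_disp_um=15.0, gap_max=1)
        seen = set()
        for tr in trajs:
            for key in tr.detection_indices:
                assert key not in seen
                seen.add(key)


class TestFlagMitosis:
    def _division_frames(self, t_div=5, n_frames=12, with_daughter_tracks=True):
        frames = []
        for t in range(n_frames):
            dets = [(40.0, 0.0, 0.0)]  # bystander
            if t < t_div:
                dets.append((10.0, 0.0, 0.0))
            else:
                dets.append((8.0, 0.0, 0.0))
                dets.append((12.0, 0.0, 0.0))
            frames.append(_dets(t, dets))
        return frames

    def test_division_flags_parent_and_daughters(self):
        frames = self._division_frames()
        trajs = track.link_tracks(frames, max_disp_um=6.0)
        track.flag_mitosis(trajs, frames, split_radius_um=6.0)
        flagged = [tr for tr in trajs if tr.mitosis_flag]
        clean = [tr for tr in trajs if not tr.mitosis_flag]
        # parent (continued into one daughter) + the new daughter track
        assert len(flagged) == 2
        assert all(tr.excluded for tr in flagged)
        # bystander untouched
        assert len(clean) == 1
        assert clean[0].centroids_um[0][0] == pytest.approx(40.0)

    def test_no_divisions_no_flags(self):
        frames = [_dets(t, [(0.0, 0.0, 0.0), (30.0, 0.0, 0.0)]) for t in range(8)]
        trajs = track.link_tracks(frames, max_disp_um=6.0)
        track.flag_mitosis(trajs, frames)
        assert not any(tr.mitosis_flag for tr in trajs)

    def test_division_at_final_frame_flags_parent_only(self):
        """Daughters appearing only in the last frame are too short to form
        tracks, but the parent is still flagged from raw detections."""
        frames = self._division_frames(t_div=11, n_frames=12)
        trajs = track.link_tracks(frames, max_disp_um=6.0, min_track_len=3)
        track.flag_mitosis(trajs, frames, split_radius_um=6.0)
        parents = [tr for tr in trajs if tr.mitosis_flag]
        assert len(parents) == 1
        assert parents[0].centroids_um[0][0] == pytest.approx(10.0)

    def test_ground_truth_scene_division_flagged(self):
        scene = sg.generate_scene(
            "wildtype", rng_seed=9, n_boundaries=2, duration_s=300.0,
            n_dividing_cells=1, include_stalk=False,
        )
        movie = sg.render_movie(scene, shot_noise=False, read_noise_sd=0.0)
        dets = track.detect_movie(movie)
        trajs = track.link_tracks(dets, max_disp_um=6.0, min_track_len=3)
        track.flag_mitosis(trajs, dets, split_radius_um=6.0)
        flagged = [tr for tr in trajs if tr.mitosis_flag]
        assert len(flagged) >= 2  # parent(+bridged daughter) and new daughter
        # the flagged tracks sit where the ground-truth division happened
        parent = next(c for c in scene.cells if c.cell_id == "div0_parent")
        ok = np.isfinite(parent.trajectory_um).all(axis=1)
        p_end = parent.trajectory_um[ok][-1]
        assert any(
            np.linalg.norm(tr.centroids_um[-1] - p_end) < 8.0 for tr in flagged
        )


class TestTrackingFidelity:
    def test_perfect_links_on_noise_free_movie(self):
        scene = sg.generate_scene("wildtype", rng_seed=12, n_boundaries=3,
                                  duration_s=300.0)
        movie = sg.render_movie(scene, shot_noise=False, read_noise_sd=0.0)
        dets = track.detect_movie(movie)
        trajs = track.link_tracks(dets, max_disp_um=6.0, min_track_len=5)
        ev = track.evaluate_tracking(trajs, scene.gt_positions(), movie.n_frames)
        assert ev["link_recall"] == 1.0
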