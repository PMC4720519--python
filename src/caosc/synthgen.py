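"""Ground-truth scene and movie generator.

Emulates in-vivo two-channel light-sheet recordings of zebrafish trunk
endothelium: a nuclear label (channel ``nuclear``) for tracking and a
cytoplasmic Ca2+ indicator (channel ``indicator``) whose intensity follows
each cell's spike train.  Every generated object carries its ground truth, so
tracking, extraction and oscillation calls can be scored against known
answers without touching generator internals.

Model choices
-------------
* Spike trains are homogeneous Poisson processes thinned by a hard refractory
  period (default 20 s) -- the simplest process that is sustained and
  non-periodic while keeping consecutive spikes resolvable at 5-s sampling.
  The long-run spike rate of this process is rate / (1 + rate * refractory).
* Each spike rises linearly over its rise time (drawn uniformly on
  5.6-18.7 s, the observed in-vivo range) and decays exponentially
  (default tau 8 s, fast enough that consecutive spikes separated by the
  refractory period remain distinct local maxima).  Amplitudes are uniform on 1.5-2.5 dF/F0, so every
  generated spike stays above the cohort-calibrated oscillation threshold
  (20% of the largest responses) even after 5-s frame sampling.
* Baseline indicator expression varies between cells (lognormal, CV 0.3).
* Rendering: nuclei are 3D Gaussian blobs (sigma 2 µm) in the nuclear
  channel; the indicator channel is a wider Gaussian blob (sigma 4 µm)
  whose brightest voxel equals the cell's fluorescence value at that frame.
  Camera noise is Poisson shot noise plus Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .extract import FluorescenceTrace

__all__ = [
    "SpikeTrain",
    "CellSpec",
    "GroundTruthScene",
    "ScenarioConfig",
    "PRESETS",
    "generate_spike_train",
    "render_trace",
    "generate_scene",
    "render_movie",
]

ROLES = ("tip", "stalk", "da")

DEFAULT_REFRACTORY_S = 20.0
DEFAULT_AMPLITUDE_RANGE_DFF = (1.5, 2.5)
DEFAULT_RISE_RANGE_S = (5.6, 18.7)
DEFAULT_DECAY_S = 8.0


def effective_rate_per_min(rate_per_min: float, refractory_s: float) -> float:
    """Long-run spike rate of a Poisson process thinned by a hard refractory
    period (accepted inter-spike intervals are refractory + Exp(rate))."""
    lam = rate_per_min / 60.0
    return 60.0 * lam / (1.0 + lam * refractory_s)


@dataclass
class SpikeTrain:
    """Ground-truth Ca2+ rise onsets with per-spike kinetics."""

    spike_times_s: np.ndarray
    amplitudes_dff: np.ndarray
    rise_times_s: np.ndarray
    decay_times_s: np.ndarray
    refractory_s: float = 0.0

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        self.amplitudes_dff = np.asarray(self.amplitudes_dff, dtype=float)
        self.rise_times_s = np.asarray(self.rise_times_s, dtype=float)
        self.decay_times_s = np.asarray(self.decay_times_s, dtype=float)
        n = len(self.spike_times_s)
        for arr, name in (
            (self.amplitudes_dff, "amplitudes_dff"),
            (self.rise_times_s, "rise_times_s"),
            (self.decay_times_s, "decay_times_s"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} must match spike_times_s in length")
        if n:
            gaps = np.diff(self.spike_times_s)
            if np.any(gaps <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.refractory_s > 0 and np.any(gaps < self.refractory_s - 1e-9):
                raise ValueError("spikes closer than the refractory period")
            if np.any(self.amplitudes_dff <= 0):
                raise ValueError("amplitudes must be positive")

    def __len__(self) -> int:
        return len(self.spike_times_s)


def generate_spike_train(
    rate_per_min: float,
    duration_s: float,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    rng_seed: int = 0,
    amplitude_range_dff: tuple[float, float] = DEFAULT_AMPLITUDE_RANGE_DFF,
    rise_range_s: tuple[float, float] = DEFAULT_RISE_RANGE_S,
    decay_s: float = DEFAULT_DECAY_S,
) -> SpikeTrain:
    """Sample a refractory-thinned Poisson spike train on [0, duration_s).

    Candidate events are homogeneous Poisson at ``rate_per_min``; a candidate
    closer than ``refractory_s`` to the last accepted spike is discarded.
    Deterministic for a fixed ``rng_seed``.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    if refractory_s < 0:
        raise ValueError("refractory_s must be >= 0")
    rng = np.random.default_rng(rng_seed)
    lam = rate_per_min / 60.0
    if lam == 0 or duration_s == 0:
        times = np.empty(0)
    else:
        n_cand = rng.poisson(lam * duration_s)
        cand = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
        accepted: list[float] = []
        for t in cand:
            if not accepted or t - accepted[-1] >= refractory_s:
                accepted.append(t)
        times = np.asarray(accepted)
    n = len(times)
    amps = rng.uniform(*amplitude_range_dff, size=n)
    rises = rng.uniform(*rise_range_s, size=n)
    decays = np.full(n, decay_s)
    return SpikeTrain(times, amps, rises, decays, refractory_s=refractory_s)


def spike_kernel_dff(t_s: np.ndarray, train: SpikeTrain) -> np.ndarray:
    """Noise-free dF/F0 contribution of all spikes at the given times:
    linear rise to the spike amplitude, then exponential decay."""
    t_s = np.asarray(t_s, dtype=float)
    dff = np.zeros_like(t_s)
    for t0, a, rise, decay in zip(
        train.spike_times_s,
        train.amplitudes_dff,
        train.rise_times_s,
        train.decay_times_s,
    ):
        dt = t_s - t0
        rising = (dt >= 0) & (dt < rise)
        falling = dt >= rise
        dff[rising] += a * dt[rising] / rise
        dff[falling] += a * np.exp(-(dt[falling] - rise) / decay)
    return dff


def render_trace(
    train: SpikeTrain,
    baseline_F0: float,
    acquisition: AcquisitionConfig,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    cell_id: object = "synthetic",
) -> FluorescenceTrace:
    """Sample F(t) = F0 * (1 + spike kernel) + Gaussian noise at frame times."""
    if baseline_F0 <= 0:
        raise ValueError("baseline_F0 must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = acquisition.frame_times_s
    F = baseline_F0 * (1.0 + spike_kernel_dff(t, train))
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        F = F + rng.normal(0.0, noise_sd, size=len(t))
    return FluorescenceTrace(cell_id=cell_id, t_s=t, F=np.clip(F, 0.0, None))


@dataclass
class CellSpec:
    """One ground-truth cell: role, nucleus trajectory, baseline and spikes.

    ``trajectory_um`` is (n_frames, 3) in (x, y, z) µm; NaN rows mean the
    cell is absent at that frame (e.g. before/after a division).
    """

    cell_id: str
    role: str
    trajectory_um: np.ndarray
    baseline_F0: float
    spike_train: SpikeTrain
    mitosis_interval_s: tuple[float, float] | None = None
    boundary_index: int | None = None
    side: str = "left"
    budding: bool = False
    following_tip: bool = False
    nuclear_intensity: float = 150.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        self.trajectory_um = np.asarray(self.trajectory_um, dtype=float)
        if self.baseline_F0 <= 0:
            raise ValueError("baseline_F0 must be > 0")

    def present(self, frame: int) -> bool:
        return bool(np.isfinite(self.trajectory_um[frame]).all())


@dataclass
class GroundTruthScene:
    cells: list[CellSpec]
    somite_boundaries_x_um: np.ndarray
    acquisition: AcquisitionConfig
    scenario: "ScenarioConfig | None" = None

    def __post_init__(self) -> None:
        self.somite_boundaries_x_um = np.asarray(self.somite_boundaries_x_um, dtype=float)
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")
        if np.any(np.diff(self.somite_boundaries_x_um) <= 0):
            raise ValueError("somite boundaries must be sorted ascending")
        ez, ey, ex = self.acquisition.volume_extent_um
        for c in self.cells:
            pos = c.trajectory_um
            ok = np.isfinite(pos).all(axis=1)
            if ok.any():
                p = pos[ok]
                if (
                    p[:, 0].min() < 0 or p[:, 0].max() > ex
                    or p[:, 1].min() < 0 or p[:, 1].max() > ey
                    or p[:, 2].min() < 0 or p[:, 2].max() > ez
                ):
                    raise ValueError(
                        f"cell {c.cell_id} trajectory leaves the imaged volume"
                    )

    def gt_positions(self) -> dict:
        """cell_id -> (frames, (n,3) x/y/z µm positions) for present frames."""
        out = {}
        for c in self.cells:
            ok = np.isfinite(c.trajectory_um).all(axis=1)
            out[c.cell_id] = (np.nonzero(ok)[0], c.trajectory_um[ok])
        return out

    def noise_free_traces(self) -> dict:
        return {
            c.cell_id: render_trace(
                c.spike_train, c.baseline_F0, self.acquisition, noise_sd=0.0,
                cell_id=c.cell_id,
            )
            for c in self.cells
        }


@dataclass
class ScenarioConfig:
    """Parameters of a generated cohort; presets fill these for the standard
    experimental conditions."""

    name: str = "wildtype"
    n_boundaries: int = 8
    boundary_spacing_um: float = 26.0
    rate_tip_per_min: float = 1.2
    rate_stalk_per_min: float = 0.6
    rate_da_per_min: float = 0.0
    two_budding_fraction: float = 0.0  # fraction of boundaries with 2 budding cells
    include_stalk: bool = True
    n_da_per_boundary: int = 1
    n_dividing_cells: int = 0
    refractory_s: float = DEFAULT_REFRACTORY_S
    amplitude_range_dff: tuple[float, float] = DEFAULT_AMPLITUDE_RANGE_DFF
    rise_range_s: tuple[float, float] = DEFAULT_RISE_RANGE_S
    decay_s: float = DEFAULT_DECAY_S
    baseline_F0_mean: float = 100.0
    baseline_F0_cv: float = 0.3
    tip_speed_um_per_min: float = 0.4
    stalk_speed_um_per_min: float = 0.2
    jitter_sd_um: float = 0.15
    duration_s: float = 1000.0
    frame_interval_s: float = 5.0
    z_step_um: float = 4.0
    xy_pixel_um: float = 1.0
    side: str = "left"


PRESETS: dict[str, dict] = {
    # tip > stalk > da(=0) oscillation rates, one budding tip per boundary
    "wildtype": {},
    # Vegfr inhibition abolishes all oscillations
    "vegfr_inhibited": {
        "rate_tip_per_min": 0.0,
        "rate_stalk_per_min": 0.0,
        "rate_da_per_min": 0.0,
    },
    # dll4 knockdown: two oscillating budding neighbours at most boundaries
    "dll4_morphant": {
        "two_budding_fraction": 0.8,
        "include_stalk": False,
    },
}


def scenario_from_preset(preset: str, **overrides) -> ScenarioConfig:
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available presets: {sorted(PRESETS)}"
        )
    params = dict(PRESETS[preset])
    params.update(overrides)
    return replace(ScenarioConfig(name=preset), **params)


def _ou_jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Mean-reverting positional jitter; per-frame steps stay small."""
    x = np.zeros(n)
    theta = 0.5
    for i in range(1, n):
        x[i] = x[i - 1] * (1 - theta) + rng.normal(0.0, sd)
    return x


def generate_scene(
    scenario: "ScenarioConfig | str" = "wildtype",
    rng_seed: int = 0,
    **overrides,
) -> GroundTruthScene:
    """Build a ground-truth scene for one cohort.

    Geometry: the dorsal aorta runs along x at the bottom of the volume;
    somite boundaries are evenly spaced along x; budding (tip/stalk) cells
    sit just anterior to a boundary and migrate dorsally (+y); non-budding
    DA cells are quasi-static between boundaries.  Reproducible under seed.
    """
    if isinstance(scenario, str):
        cfg = scenario_from_preset(scenario, **overrides)
    elif overrides:
        cfg = replace(scenario, **overrides)
    else:
        cfg = scenario
    rng = np.random.default_rng(rng_seed)

    dt = cfg.frame_interval_s
    n_frames = int(round(cfg.duration_s / dt))
    t = np.arange(n_frames) * dt

    spacing = cfg.boundary_spacing_um
    boundaries = spacing * (1.0 + np.arange(cfg.n_boundaries))
    x_extent = spacing * (cfg.n_boundaries + 1)
    y_base = 6.0
    max_rise = max(cfg.tip_speed_um_per_min, cfg.stalk_speed_um_per_min) * cfg.duration_s / 60.0
    y_extent = y_base + 8.0 + max_rise + 6.0
    z_mid_plane = 3
    nz = 7
    acq = AcquisitionConfig(
        frame_interval_s=dt,
        z_step_um=cfg.z_step_um,
        xy_pixel_um=cfg.xy_pixel_um,
        duration_s=cfg.duration_s,
        volume_shape=(
            nz,
            int(np.ceil(y_extent / cfg.xy_pixel_um)) + 1,
            int(np.ceil(x_extent / cfg.xy_pixel_um)) + 1,
        ),
        rng_seed=rng_seed,
    )
    z0 = z_mid_plane * cfg.z_step_um

    def _baseline() -> float:
        cv = cfg.baseline_F0_cv
        if cv <= 0:
            return cfg.baseline_F0_mean
        s = np.sqrt(np.log1p(cv * cv))
        return float(
            rng.lognormal(np.log(cfg.baseline_F0_mean) - s * s / 2.0, s)
        )

    def _train(rate: float) -> SpikeTrain:
        return generate_spike_train(
            rate,
            cfg.duration_s,
            refractory_s=cfg.refractory_s,
            rng_seed=int(rng.integers(2**31)),
            amplitude_range_dff=cfg.amplitude_range_dff,
            rise_range_s=cfg.rise_range_s,
            decay_s=cfg.decay_s,
        )

    def _trajectory(x0: float, y0: float, speed_um_per_min: float) -> np.ndarray:
        pos = np.empty((n_frames, 3))
        pos[:, 0] = x0 + _ou_jitter(rng, n_frames, cfg.jitter_sd_um)
        pos[:, 1] = y0 + speed_um_per_min * t / 60.0 + _ou_jitter(rng, n_frames, cfg.jitter_sd_um)
        pos[:, 2] = z0 + _ou_jitter(rng, n_frames, cfg.jitter_sd_um)
        return pos

    cells: list[CellSpec] = []
    for b_idx, xb in enumerate(boundaries):
        n_budding = 2 if rng.random() < cfg.two_budding_fraction else 1
        for j in range(n_budding):
            x0 = xb - 2.0 - 9.0 * j
            cells.append(
                CellSpec(
                    cell_id=f"b{b_idx}_tip{j}",
                    role="tip",
                    trajectory_um=_trajectory(x0, y_base + 8.0, cfg.tip_speed_um_per_min),
                    baseline_F0=_baseline(),
                    spike_train=_train(cfg.rate_tip_per_min),
                    boundary_index=b_idx,
                    side=cfg.side,
                    budding=True,
                )
            )
        if cfg.include_stalk:
            cells.append(
                CellSpec(
                    cell_id=f"b{b_idx}_stalk",
                    role="stalk",
                    trajectory_um=_trajectory(xb - 2.0, y_base, cfg.stalk_speed_um_per_min),
                    baseline_F0=_baseline(),
                    spike_train=_train(cfg.rate_stalk_per_min),
                    boundary_index=b_idx,
                    side=cfg.side,
                    budding=True,
                    following_tip=True,
                )
            )
        for k in range(cfg.n_da_per_boundary):
            xd = xb - spacing / 2.0 + 4.0 * k
            cells.append(
                CellSpec(
                    cell_id=f"b{b_idx}_da{k}",
                    role="da",
                    trajectory_um=_trajectory(xd, y_base, 0.0),
                    baseline_F0=_baseline(),
                    spike_train=_train(cfg.rate_da_per_min),
                    boundary_index=b_idx,
                    side=cfg.side,
                )
            )

    # optional dividing cells: a quiescent DA cell splits mid-recording into
    # two daughters offset along x; parent absent after, daughters before.
    for m in range(cfg.n_dividing_cells):
        xb = boundaries[m % cfg.n_boundaries]
        x0 = xb - spacing / 2.0
        k_div = n_frames // 2
        t_div = k_div * dt
        # two z-planes above the aorta so the divider and its daughters stay
        # resolvable from the regular DA cells
        z_off = 2.0 * cfg.z_step_um
        parent_traj = _trajectory(x0, y_base, 0.0)
        parent_traj[:, 2] += z_off
        parent = parent_traj.copy()
        parent[k_div:] = np.nan
        d1 = _trajectory(x0 - 4.0, y_base, 0.0)
        d2 = _trajectory(x0 + 4.0, y_base, 0.0)
        d1[:, 2] += z_off
        d2[:, 2] += z_off
        d1[:k_div] = np.nan
        d2[:k_div] = np.nan
        quiet = SpikeTrain(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
        common = dict(role="da", side=cfg.side, boundary_index=int(m % cfg.n_boundaries))
        cells.append(
            CellSpec(
                cell_id=f"div{m}_parent", trajectory_um=parent,
                baseline_F0=_baseline(), spike_train=quiet,
                mitosis_interval_s=(t_div - dt, t_div + dt), **common,
            )
        )
        for tag, dtraj in (("d1", d1), ("d2", d2)):
            cells.append(
                CellSpec(
                    cell_id=f"div{m}_{tag}", trajectory_um=dtraj,
                    baseline_F0=_baseline(), spike_train=quiet,
                    mitosis_interval_s=(t_div - dt, t_div + dt), **common,
                )
            )

    return GroundTruthScene(
        cells=cells, somite_boundaries_x_um=boundaries, acquisition=acq,
        scenario=cfg,
    )


def _add_blob(
    canvas: np.ndarray,
    center_um: np.ndarray,
    amplitude: float,
    sigma_um: float,
    voxel_size_zyx_um: tuple[float, float, float],
) -> None:
    """Max-composite a Gaussian blob whose brightest voxel equals
    ``amplitude`` into the (Z, Y, X) canvas."""
    cx, cy, cz = (float(v) for v in center_um)
    sz, sy, sx = voxel_size_zyx_um
    nz, ny, nx = canvas.shape
    half = 3.0 * sigma_um

    def _rng(c, step, n):
        return (
            max(0, int(np.ceil((c - half) / step))),
            min(n - 1, int(np.floor((c + half) / step))),
        )

    zlo, zhi = _rng(cz, sz, nz)
    ylo, yhi = _rng(cy, sy, ny)
    xlo, xhi = _rng(cx, sx, nx)
    if zlo > zhi or ylo > yhi or xlo > xhi:
        return
    zz = (np.arange(zlo, zhi + 1) * sz - cz) ** 2
    yy = (np.arange(ylo, yhi + 1) * sy - cy) ** 2
    xx = (np.arange(xlo, xhi + 1) * sx - cx) ** 2
    d2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    g = np.exp(-0.5 * d2 / (sigma_um * sigma_um))
    g *= amplitude / g.max()
    sub = canvas[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1]
    np.maximum(sub, g, out=sub)


def render_movie(
    scene: GroundTruthScene,
    shot_noise: bool = True,
    read_noise_sd: float = 2.0,
    background: float = 10.0,
    nucleus_sigma_um: float = 2.0,
    cyto_sigma_um: float = 4.0,
    rng_seed: int = 0,
):
    """Render a two-channel (T, Z, Y, X) movie from a ground-truth scene.

    Channel ``nuclear``: one nucleus blob per present cell.  Channel
    ``indicator``: one cytoplasm blob per cell whose peak voxel equals the
    cell's noise-free fluorescence trace at that frame.  Overlapping blobs
    composite by maximum (an occluding brighter cell wins), backgrounds by
    maximum with the flat background level.  Camera noise: Poisson shot noise
    on the expected photon count plus Gaussian read noise.
    """
    from .io_formats import MovieHandle  # local import to avoid cycle

    acq = scene.acquisition
    nz, ny, nx = acq.volume_shape
    n_frames = acq.n_frames
    voxel = acq.voxel_size_zyx_um
    ez, ey, ex = acq.volume_extent_um

    for c in scene.cells:
        pos = c.trajectory_um
        ok = np.isfinite(pos).all(axis=1)
        if ok.any():
            p = pos[ok]
            if (
                p[:, 0].min() < 0 or p[:, 0].max() > ex
                or p[:, 1].min() < 0 or p[:, 1].max() > ey
                or p[:, 2].min() < 0 or p[:, 2].max() > ez
            ):
                raise ValueError(f"cell {c.cell_id} leaves the rendered volume")

    traces = scene.noise_free_traces()
    rng = np.random.default_rng(rng_seed)
    ch_nuc = np.empty((n_frames, nz, ny, nx), dtype=np.float32)
    ch_ind = np.empty((n_frames, nz, ny, nx), dtype=np.float32)
    for tfr in range(n_frames):
        nuc = np.full((nz, ny, nx), background)
        ind = np.full((nz, ny, nx), background)
        for c in scene.cells:
            if not c.present(tfr):
                continue
            center = c.trajectory_um[tfr]
            _add_blob(nuc, center, c.nuclear_intensity, nucleus_sigma_um, voxel)
            _add_blob(ind, center, traces[c.cell_id].F[tfr], cyto_sigma_um, voxel)
        for canvas, out in ((nuc, ch_nuc), (ind, ch_ind)):
            if shot_noise:
                canvas = rng.poisson(canvas).astype(np.float64)
            if read_noise_sd > 0:
                canvas = canvas + rng.normal(0.0, read_noise_sd, size=canvas.shape)
            out[tfr] = np.clip(canvas, 0.0, None)
    return MovieHandle(
        channels={"nuclear": ch_nuc, "indicator": ch_ind},
        xy_pixel_um=acq.xy_pixel_um,
        z_step_um=acq.z_step_um,
        frame_interval_s=acq.frame_interval_s,
    )


def scene_tables(scene: GroundTruthScene) -> dict[str, pd.DataFrame]:
    """Ground-truth tables: cell annotations, spike times, boundaries."""
    ann_rows, spike_rows = [], []
    for c in scene.cells:
        ok = np.isfinite(c.trajectory_um).all(axis=1)
        first = int(np.nonzero(ok)[0][0]) if ok.any() else 0
        x0, y0, z0 = c.trajectory_um[first]
        ann_rows.append(
            dict(
                cell_id=c.cell_id, role=c.role, side=c.side,
                budding=c.budding, following_tip=c.following_tip,
                boundary_index=-1 if c.boundary_index is None else c.boundary_index,
                x_um=x0, y_um=y0, z_um=z0,
            )
        )
        tr = c.spike_train
        for i in range(len(tr)):
            spike_rows.append(
                dict(
                    cell_id=c.cell_id,
                    spike_time_s=tr.spike_times_s[i],
                    amplitude_dff=tr.amplitudes_dff[i],
                    rise_time_s=tr.rise_times_s[i],
                    decay_time_s=tr.decay_times_s[i],
                )
            )
    from .io_formats import SCHEMAS

    annotations = pd.DataFrame(ann_rows, columns=SCHEMAS["annotations"])
    spikes = pd.DataFrame(spike_rows, columns=SCHEMAS["spikes"])
    boundaries = pd.DataFrame({"x_um": scene.somite_boundaries_x_um})
    return {"annotations": annotations, "spikes": spikes, "boundaries": boundaries}
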