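"""End-to-end pipeline orchestration and group statistics.

``run_pipeline`` drives movie synthesis -> nucleus tracking -> ROI trace
extraction -> dF/F0 quantification -> synchrony / spatial summaries ->
group comparisons, writing every stage table plus ``summary.json`` into a
run directory.  Runs are fully deterministic under a fixed seed (no
timestamps in any output), so two runs of the same configuration produce
byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import extract, io_formats, oscillate, synthgen, syncspace, track

__all__ = ["GroupComparison", "compare_groups", "PipelineConfig", "run_pipeline"]


@dataclass
class GroupComparison:
    """Two-sample comparison in the style of the original analysis:
    Student's t test (equal variances), significant at p < 0.05."""

    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    t_statistic: float
    p_value: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "n": list(self.n),
            "means": list(self.means),
            "sds": list(self.sds),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def compare_groups(
    values_a,
    values_b,
    labels: tuple[str, str] = ("A", "B"),
    equal_var: bool = True,
    paired: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided two-sample t test.

    Defaults to the classical equal-variance (Student's) form; ``equal_var=
    False`` gives Welch's test and ``paired=True`` the paired test.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal group sizes")
        t_stat, p = stats.ttest_rel(a, b)
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    t_stat, p = float(t_stat), float(p)
    if np.isnan(t_stat) and np.allclose(a.mean(), b.mean()):
        # both groups constant and equal: no evidence of a difference
        t_stat, p = 0.0, 1.0
    return GroupComparison(
        group_labels=labels,
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        t_statistic=t_stat,
        p_value=p,
        significant=bool(p < alpha),
    )


@dataclass
class PipelineConfig:
    """One pipeline run: a scenario preset plus stage parameters."""

    preset: str = "wildtype"
    seed: int = 1
    out_dir: str = "runs/wildtype"
    scenario_overrides: dict = field(default_factory=dict)
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    detect_threshold: float = 50.0
    max_disp_um: float = 6.0
    gap_max: int = 1
    min_track_len: int = 5
    split_radius_um: float = 6.0
    baseline_window_s: float = 50.0
    min_separation_s: float = 10.0
    threshold_override: float | None = None
    wildtype_cohort: str = "wildtype"
    sync_window_s: float = 10.0
    save_movie: bool = False
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages for one scenario; returns the run directory.

    Stage failures raise with the failing stage named; tables written before
    the failure are retained for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **params) -> None:
        payload = json.dumps(params, sort_keys=True, default=str)
        log_lines.append(f"{stage} {payload}")

    stage = "synth"
    try:
        scene = synthgen.generate_scene(
            config.preset, rng_seed=config.seed, **config.scenario_overrides
        )
        tables = synthgen.scene_tables(scene)
        for name, df in tables.items():
            io_formats.write_table(df, out / f"{name}.csv", name)
        movie = synthgen.render_movie(
            scene,
            shot_noise=config.shot_noise,
            read_noise_sd=config.read_noise_sd,
            rng_seed=config.seed + 1,
        )
        if config.save_movie:
            io_formats.write_movie(movie, out / "movie")
        log(stage, preset=config.preset, seed=config.seed,
            n_cells=len(scene.cells), volume_shape=movie.volume_shape,
            n_frames=movie.n_frames, overrides=config.scenario_overrides)

        stage = "track"
        detections = track.detect_movie(movie, threshold=config.detect_threshold)
        trajectories = track.link_tracks(
            detections,
            max_disp_um=config.max_disp_um,
            gap_max=config.gap_max,
            min_track_len=config.min_track_len,
        )
        track.flag_mitosis(trajectories, detections, config.split_radius_um)
        matches = track.annotate_tracks(trajectories, tables["annotations"])
        # keep one (longest) trajectory per annotated ground-truth cell
        by_gt: dict[str, track.NucleusTrajectory] = {}
        traj_by_id = {tr.cell_id: tr for tr in trajectories}
        for tid, row in matches.items():
            tr = traj_by_id[tid]
            cur = by_gt.get(row["cell_id"])
            if cur is None or len(tr) > len(cur):
                by_gt[row["cell_id"]] = tr
        tracking_eval = track.evaluate_tracking(
            trajectories, scene.gt_positions(), movie.n_frames
        )
        track_rows = []
        for tr in trajectories:
            for f, c in zip(tr.frames, tr.centroids_um):
                track_rows.append(
                    dict(cell_id=tr.cell_id, frame=int(f),
                         t_s=float(f) * movie.frame_interval_s,
                         x_um=c[0], y_um=c[1], z_um=c[2],
                         mitosis_flag=tr.mitosis_flag, excluded=tr.excluded)
                )
        io_formats.write_table(
            pd.DataFrame(track_rows, columns=io_formats.SCHEMAS["tracks"]),
            out / "tracks.csv", "tracks",
        )
        log(stage, n_trajectories=len(trajectories),
            n_annotated=len(by_gt), link_recall=tracking_eval["link_recall"],
            max_disp_um=config.max_disp_um, gap_max=config.gap_max)

        stage = "extract"
        ann = tables["annotations"].set_index("cell_id")
        analysed = {
            gt_id: tr for gt_id, tr in sorted(by_gt.items()) if not tr.excluded
        }
        kept_trajs = list(analysed.values())
        rois, traces = {}, {}
        trace_rows = []
        for gt_id, tr in analysed.items():
            roi = extract.fit_roi_diameter(tr, kept_trajs, movie.n_frames)
            trace = extract.extract_trace(movie, roi, tr)
            trace.cell_id = gt_id
            rois[gt_id], traces[gt_id] = roi, trace
            for f in range(movie.n_frames):
                trace_rows.append(
                    dict(cell_id=gt_id, frame=f, t_s=trace.t_s[f], F=trace.F[f],
                         roi_diameter_um=roi.diameter_um,
                         overlap_flag=roi.overlap_flag)
                )
        io_formats.write_table(
            pd.DataFrame(trace_rows, columns=io_formats.SCHEMAS["traces"]),
            out / "traces.csv", "traces",
        )
        log(stage, n_cells=len(traces))

        stage = "quantify"
        dffs = {}
        for gt_id, trace in traces.items():
            F0 = oscillate.compute_baseline(trace, config.baseline_window_s)
            dffs[gt_id] = oscillate.compute_dff(trace, F0)
        if config.threshold_override is not None:
            thr = oscillate.DetectionThreshold(
                reference_100pct=config.threshold_override / oscillate.THRESHOLD_FRACTION,
                threshold=config.threshold_override,
                cohort_id=f"{config.wildtype_cohort}-override",
            )
        else:
            thr = oscillate.calibrate_threshold(
                list(dffs.values()),
                min_separation_s=config.min_separation_s,
                cohort_id=config.wildtype_cohort,
            )
        peaks = {
            gt_id: oscillate.detect_peaks(d, thr, config.min_separation_s)
            for gt_id, d in dffs.items()
        }
        metrics = {
            gt_id: oscillate.oscillation_metrics(dffs[gt_id], peaks[gt_id])
            for gt_id in dffs
        }
        dff_rows, peak_rows, metric_rows = [], [], []
        for gt_id, d in dffs.items():
            for f in range(len(d)):
                dff_rows.append(dict(cell_id=gt_id, frame=f, t_s=d.t_s[f],
                                     dff=d.dff[f], F0=d.F0))
            for p in peaks[gt_id]:
                peak_rows.append(
                    dict(cell_id=gt_id, apex_frame=p.apex_frame,
                         apex_time_s=p.apex_time_s, apex_dff=p.apex_dff,
                         prominence=p.prominence,
                         onset_time_s=np.nan if p.onset_time_s is None else p.onset_time_s,
                         time_to_peak_s=np.nan if p.time_to_peak_s is None else p.time_to_peak_s)
                )
            m = metrics[gt_id]
            metric_rows.append(
                dict(cell_id=gt_id, n_peaks=m.n_peaks,
                     frequency_per_min=m.frequency_per_min, mean_dff=m.mean_dff,
                     observed_duration_s=m.observed_duration_s,
                     oscillating=m.oscillating)
            )
        io_formats.write_table(pd.DataFrame(dff_rows, columns=io_formats.SCHEMAS["dff"]),
                               out / "dff.csv", "dff")
        io_formats.write_table(pd.DataFrame(peak_rows, columns=io_formats.SCHEMAS["peaks"]),
                               out / "peaks.csv", "peaks")
        metrics_df = pd.DataFrame(metric_rows, columns=io_formats.SCHEMAS["metrics"])
        io_formats.write_table(metrics_df, out / "metrics.csv", "metrics")
        (out / "threshold.json").write_text(json.dumps(
            {"reference_100pct": thr.reference_100pct, "threshold": thr.threshold,
             "cohort_id": thr.cohort_id, "n_pooled_peaks": thr.n_pooled_peaks,
             "fraction": thr.fraction},
            indent=2, sort_keys=True))
        log(stage, threshold=thr.threshold, reference=thr.reference_100pct,
            n_pooled_peaks=thr.n_pooled_peaks)

        stage = "synchrony"
        rise_times = {}
        for gt_id, pks in peaks.items():
            rise_times[gt_id] = np.array([
                p.onset_time_s if p.onset_time_s is not None else p.apex_time_s
                for p in pks
            ])
        sync_rows = []
        for gt_id in analysed:
            row = ann.loc[gt_id]
            if row["role"] != "tip":
                continue
            partners = [
                other for other in analysed
                if other != gt_id
                and ann.loc[other]["role"] == "stalk"
                and ann.loc[other]["boundary_index"] == row["boundary_index"]
            ]
            for other in partners:
                res = syncspace.classify_synchrony(
                    np.sort(rise_times[gt_id]), np.sort(rise_times[other]),
                    window_s=config.sync_window_s, cell_a=gt_id, cell_b=other,
                )
                sync_rows.append(
                    dict(cell_a=gt_id, cell_b=other,
                         n_rises_a=len(res.labels_a), n_rises_b=len(res.labels_b),
                         pct_synchronous_a=res.pct_synchronous_a,
                         pct_synchronous_b=res.pct_synchronous_b,
                         window_s=res.window_s)
                )
        sync_df = pd.DataFrame(sync_rows, columns=io_formats.SCHEMAS["synchrony"])
        io_formats.write_table(sync_df, out / "synchrony.csv", "synchrony")

        stage = "spatial"
        region_rows = []
        cells_for_counts = []
        import warnings as _warnings

        for gt_id in analysed:
            row = ann.loc[gt_id]
            with _warnings.catch_warnings():
                # cells anterior to the first boundary are legitimately
                # unassigned; no need to warn per cell here
                _warnings.simplefilter("ignore", UserWarning)
                reg = syncspace.assign_region(
                    row["x_um"], scene.somite_boundaries_x_um, cell_id=gt_id
                )
            region_rows.append(
                dict(cell_id=gt_id,
                     region=-1 if reg.region is None else reg.region,
                     left_x_um=reg.left_x_um, right_x_um=reg.right_x_um,
                     nucleus_x_um=reg.nucleus_x_um)
            )
            cells_for_counts.append(
                dict(cell_id=gt_id, x_um=row["x_um"],
                     oscillating=metrics[gt_id].oscillating,
                     budding=bool(row["budding"]), side=row["side"],
                     following_tip=bool(row["following_tip"]))
            )
        io_formats.write_table(
            pd.DataFrame(region_rows, columns=io_formats.SCHEMAS["regions"]),
            out / "regions.csv", "regions",
        )
        counts, category_pct = syncspace.count_oscillating_cells(
            pd.DataFrame(cells_for_counts,
                         columns=["cell_id", "x_um", "oscillating", "budding",
                                  "side", "following_tip"]),
            scene.somite_boundaries_x_um,
        )
        io_formats.write_table(
            pd.DataFrame(
                [dict(boundary_x_um=c.boundary_x_um,
                      n_oscillating=c.n_oscillating, category=c.category)
                 for c in counts],
                columns=io_formats.SCHEMAS["boundary_counts"]),
            out / "boundary_counts.csv", "boundary_counts",
        )

        stage = "report"
        roles = {gt_id: ann.loc[gt_id]["role"] for gt_id in analysed}
        by_role: dict[str, list] = {"tip": [], "stalk": [], "da": []}
        dff_by_role: dict[str, list] = {"tip": [], "stalk": [], "da": []}
        for gt_id, role in roles.items():
            by_role[role].append(metrics[gt_id].frequency_per_min)
            dff_by_role[role].append(metrics[gt_id].mean_dff)
        comparisons = {}
        for a, b in (("tip", "stalk"), ("tip", "da"), ("stalk", "da")):
            if len(by_role[a]) >= 2 and len(by_role[b]) >= 2:
                comparisons[f"{a}_vs_{b}_frequency"] = compare_groups(
                    by_role[a], by_role[b], labels=(a, b)).as_dict()
                comparisons[f"{a}_vs_{b}_mean_dff"] = compare_groups(
                    dff_by_role[a], dff_by_role[b], labels=(a, b)).as_dict()
        sync_summary = {}
        if len(sync_df):
            tot_a = int(sync_df["n_rises_a"].sum())
            tot_b = int(sync_df["n_rises_b"].sum())
            sync_a = float((sync_df["pct_synchronous_a"] / 100.0
                            * sync_df["n_rises_a"]).sum())
            sync_b = float((sync_df["pct_synchronous_b"] / 100.0
                            * sync_df["n_rises_b"]).sum())
            sync_summary = {
                "n_rises_tip": tot_a,
                "n_rises_stalk": tot_b,
                "pct_synchronous_tip": 100.0 * sync_a / tot_a if tot_a else np.nan,
                "pct_synchronous_stalk": 100.0 * sync_b / tot_b if tot_b else np.nan,
            }
        n_oscillating = int(sum(m.oscillating for m in metrics.values()))
        summary = {
            "preset": config.preset,
            "seed": config.seed,
            "n_cells_tracked": len(trajectories),
            "n_cells_analyzed": len(analysed),
            "n_cells_oscillating": n_oscillating,
            "threshold_dff": thr.threshold,
            "reference_100pct": thr.reference_100pct,
            "tracking_link_recall": tracking_eval["link_recall"],
            "frequency_per_min": {
                role: {
                    "n": len(vals),
                    "mean": float(np.mean(vals)) if vals else None,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
                }
                for role, vals in by_role.items()
            },
            "mean_dff": {
                role: {
                    "n": len(vals),
                    "mean": float(np.mean(vals)) if vals else None,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
                }
                for role, vals in dff_by_role.items()
            },
            "comparisons": comparisons,
            "synchrony": sync_summary,
            "boundary_categories_pct": {
                k: (None if np.isnan(v) else v) for k, v in category_pct.items()
            },
            "n_boundaries_with_oscillating": len(counts),
        }
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        if config.make_plots:
            _dot_plot(metrics_df, ann, out / "dotplots.png")
        for artefact in sorted(out.glob("*.csv")) + [summary_path]:
            log("hash", file=artefact.name, sha256=_sha256(artefact))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return out


def _dot_plot(metrics_df: pd.DataFrame, ann: pd.DataFrame, path: Path) -> None:
    """Per-cell frequency and mean dF/F0 dot plots by role, regenerable from
    metrics.csv alone."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = metrics_df.copy()
    df["role"] = [ann.loc[c]["role"] if c in ann.index else "?" for c in df["cell_id"]]
    roles = [r for r in ("tip", "stalk", "da") if (df["role"] == r).any()]
    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    for ax, col, label in zip(
        axes, ("frequency_per_min", "mean_dff"),
        ("Ca$^{2+}$ oscillation frequency (min$^{-1}$)", "mean $\\Delta F/F_0$"),
    ):
        for i, role in enumerate(roles):
            vals = df.loc[df["role"] == role, col]
            x = np.full(len(vals), i) + np.linspace(-0.12, 0.12, max(len(vals), 1))
            ax.plot(x, vals, "o", ms=4, alpha=0.7)
            if len(vals):
                ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k", lw=1.5)
        ax.set_xticks(range(len(roles)))
        ax.set_xticklabels(roles)
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
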