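"""dF/F0 normalisation, threshold calibration and Ca2+ rise detection.

The chain is scale-free by construction: F0 is a sliding-window baseline of
the raw trace, dF/F0 = (F - F0)/F0, and the oscillation threshold is defined
relative to the cohort's largest responses (20% of the mean of the three
highest dF/F0 peaks in oscillating wild-type cells), so multiplying raw
fluorescence by any positive constant leaves every downstream quantity
unchanged.

Baseline: the original description fixes only the window length (50 s); here
F0 is the minimum over all 50-s sliding-window means -- the quietest stretch
of the recording -- which stays robust for cells that oscillate from the
first frame.

The published threshold definition is circular (peaks are needed to set the
threshold that defines peaks); :func:`calibrate_threshold` resolves it with a
provisional absolute floor (dF/F0 >= 0.2) followed by fixed-point iteration,
which terminates because the reference is non-increasing once set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .extract import FluorescenceTrace

__all__ = [
    "DffTrace",
    "Peak",
    "DetectionThreshold",
    "OscillationMetrics",
    "compute_baseline",
    "compute_dff",
    "calibrate_threshold",
    "threshold_from_peak_heights",
    "detect_peaks",
    "time_to_peak",
    "oscillation_metrics",
]

DEFAULT_BASELINE_WINDOW_S = 50.0
DEFAULT_MIN_SEPARATION_S = 10.0
DEFAULT_ONSET_FRACTION = 0.1
PROVISIONAL_FLOOR_DFF = 0.2
THRESHOLD_FRACTION = 0.2


@dataclass
class DffTrace:
    """Normalised dF/F0 trace with its baseline F0."""

    cell_id: object
    t_s: np.ndarray
    dff: np.ndarray
    F0: float
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.t_s.shape != self.dff.shape:
            raise ValueError("t_s and dff must align")
        if not (self.F0 > 0):
            raise ValueError("F0 must be > 0")

    def __len__(self) -> int:
        return len(self.dff)

    @property
    def frame_interval_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])


@dataclass
class Peak:
    """One detected Ca2+ rise."""

    cell_id: object
    apex_frame: int
    apex_time_s: float
    apex_dff: float
    prominence: float
    onset_time_s: float | None = None
    time_to_peak_s: float | None = None


@dataclass
class DetectionThreshold:
    """Cohort-calibrated oscillation threshold.

    ``reference_100pct`` is the mean of the three highest dF/F0 peaks pooled
    over oscillating wild-type cells; an excursion of at least 20% of that
    reference counts as an oscillation.
    """

    reference_100pct: float
    threshold: float
    cohort_id: str = "wildtype"
    n_pooled_peaks: int = 0
    fraction: float = THRESHOLD_FRACTION

    def __post_init__(self) -> None:
        if abs(self.threshold - self.fraction * self.reference_100pct) > 1e-12 * max(
            1.0, self.reference_100pct
        ):
            raise ValueError("threshold must equal fraction * reference_100pct")


@dataclass
class OscillationMetrics:
    """Per-cell oscillation summary: count, frequency (min^-1), mean dF/F0."""

    cell_id: object
    n_peaks: int
    frequency_per_min: float
    mean_dff: float
    observed_duration_s: float
    oscillating: bool


def compute_baseline(
    trace: FluorescenceTrace, window_s: float = DEFAULT_BASELINE_WINDOW_S
) -> float:
    """F0 = minimum over all sliding windows of length ``window_s`` of the
    window-mean fluorescence (missing samples are excluded from the means;
    windows with fewer than half their samples valid are skipped)."""
    dt = trace.frame_interval_s
    n_win = int(round(window_s / dt))
    if n_win < 1:
        raise ValueError("window shorter than one frame")
    if len(trace) < n_win:
        raise ValueError(
            f"trace ({len(trace)} frames) shorter than the {window_s}-s "
            f"baseline window ({n_win} frames)"
        )
    s = pd.Series(trace.F)
    means = s.rolling(n_win, min_periods=max(1, n_win // 2)).mean().to_numpy()
    means = means[n_win - 1 :]
    means = means[np.isfinite(means)]
    if means.size == 0:
        raise ValueError("no baseline window with enough valid samples")
    return float(means.min())


def compute_dff(trace: FluorescenceTrace, F0: float) -> DffTrace:
    """dF/F0 = (F - F0) / F0, elementwise; missing samples stay missing."""
    if not (F0 > 0):
        raise ValueError("F0 must be > 0")
    return DffTrace(
        cell_id=trace.cell_id,
        t_s=trace.t_s,
        dff=(trace.F - F0) / F0,
        F0=float(F0),
    )


def _segments(x: np.ndarray):
    """Yield (offset, values) for maximal runs of finite samples."""
    finite = np.isfinite(x)
    if not finite.any():
        return
    idx = np.nonzero(finite)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    for s, e in zip(starts, ends):
        yield int(idx[s]), x[idx[s] : idx[e] + 1]


def _prune_by_separation(
    candidates: list[tuple[int, float, float]], min_separation_s: float, dt: float
) -> list[tuple[int, float, float]]:
    """Greedy pruning by descending apex height (ties: earlier apex wins):
    drop any candidate within < min_separation_s of an already kept apex."""
    order = sorted(candidates, key=lambda c: (-c[1], c[0]))
    kept: list[tuple[int, float, float]] = []
    for cand in order:
        if all(abs(cand[0] - k[0]) * dt >= min_separation_s for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c[0])
    return kept


def _find_onset(
    x: np.ndarray, seg_offset: int, apex_local: int, apex_value: float,
    t_s: np.ndarray, onset_fraction: float,
) -> float | None:
    """Last upward crossing of onset_fraction * apex before the apex, with
    linear interpolation between samples; None when the apex opens the
    segment or the trace never dips below the crossing level."""
    level = onset_fraction * apex_value
    i = apex_local
    while i > 0 and x[i - 1] > level:
        i -= 1
    if i == 0:
        return None
    lo, hi = x[i - 1], x[i]
    t_lo, t_hi = t_s[seg_offset + i - 1], t_s[seg_offset + i]
    if hi == lo:
        return float(t_hi)
    frac = (level - lo) / (hi - lo)
    return float(t_lo + frac * (t_hi - t_lo))


def detect_peaks(
    dff: DffTrace,
    threshold: "DetectionThreshold | float",
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    onset_fraction: float = DEFAULT_ONSET_FRACTION,
) -> list[Peak]:
    """Detect Ca2+ rises in a dF/F0 trace.

    A rise is a local maximum with apex dF/F0 >= threshold and prominence >=
    threshold relative to its enclosing troughs; apexes closer than
    ``min_separation_s`` are pruned keeping the higher one.  Plateau maxima
    resolve to the plateau midpoint.  Missing stretches split the trace; no
    peak spans a gap.
    """
    thr = threshold.threshold if isinstance(threshold, DetectionThreshold) else float(threshold)
    dt = dff.frame_interval_s
    candidates: list[tuple[int, float, float]] = []  # (global apex idx, height, prominence)
    seg_of: dict[int, tuple[int, np.ndarray]] = {}
    for offset, seg in _segments(dff.dff):
        if len(seg) < 3:
            continue
        idx, props = find_peaks(seg, height=thr, prominence=thr)
        for k, apex in enumerate(idx):
            g = offset + int(apex)
            candidates.append((g, float(seg[apex]), float(props["prominences"][k])))
            seg_of[g] = (offset, seg)
    kept = _prune_by_separation(candidates, min_separation_s, dt)
    peaks: list[Peak] = []
    for g, height, prom in kept:
        offset, seg = seg_of[g]
        onset = _find_onset(seg, offset, g - offset, height, dff.t_s, onset_fraction)
        ttp = None
        if onset is not None:
            # 10%->apex interval extrapolated to the full (linear) rise
            ttp = (float(dff.t_s[g]) - onset) / (1.0 - onset_fraction)
        peaks.append(
            Peak(
                cell_id=dff.cell_id,
                apex_frame=g,
                apex_time_s=float(dff.t_s[g]),
                apex_dff=height,
                prominence=prom,
                onset_time_s=onset,
                time_to_peak_s=ttp,
            )
        )
    return peaks


def time_to_peak(peak: Peak) -> float:
    """Rise duration of one oscillation (s); NaN when the onset was
    undetectable (apex at the trace start)."""
    return np.nan if peak.time_to_peak_s is None else float(peak.time_to_peak_s)


def threshold_from_peak_heights(
    heights,
    fraction: float = THRESHOLD_FRACTION,
    n_top: int = 3,
    cohort_id: str = "wildtype",
) -> DetectionThreshold:
    """Reference = mean of the ``n_top`` highest pooled peak heights;
    threshold = fraction * reference."""
    heights = np.sort(np.asarray(list(heights), dtype=float))[::-1]
    if len(heights) < n_top:
        raise ValueError(
            f"need at least {n_top} pooled peaks to calibrate "
            f"(got {len(heights)}); pass an explicit threshold override"
        )
    ref = float(heights[:n_top].mean())
    return DetectionThreshold(
        reference_100pct=ref,
        threshold=fraction * ref,
        cohort_id=cohort_id,
        n_pooled_peaks=int(len(heights)),
        fraction=fraction,
    )


def calibrate_threshold(
    wildtype_dff_traces: list[DffTrace],
    provisional_floor: float = PROVISIONAL_FLOOR_DFF,
    fraction: float = THRESHOLD_FRACTION,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    per_cell: bool = False,
    cohort_id: str = "wildtype",
    max_iter: int = 20,
) -> DetectionThreshold:
    """Self-calibrate the oscillation threshold on a wild-type cohort.

    Pass 1 detects provisional peaks at an absolute floor (default 0.2) to
    identify oscillating cells; the reference is the mean of the three
    highest peaks pooled across those cells (or, with ``per_cell``, the mean
    over cells of each cell's top-three mean) and the threshold is
    ``fraction`` of the reference.  Detection and reference are iterated to a
    fixed point.
    """
    if not wildtype_dff_traces:
        raise ValueError("need at least one wild-type trace")
    thr = float(provisional_floor)
    result = None
    prev_signature = None
    for _ in range(max_iter):
        per_cell_heights = []
        for tr in wildtype_dff_traces:
            pk = detect_peaks(tr, thr, min_separation_s=min_separation_s)
            if pk:
                per_cell_heights.append((tr.cell_id, [p.apex_dff for p in pk]))
        pooled = [h for _, hs in per_cell_heights for h in hs]
        if len(pooled) < 3:
            raise ValueError(
                "fewer than 3 pooled peaks in the wild-type cohort; "
                "calibration impossible -- pass an explicit threshold override"
            )
        if per_cell:
            refs = [
                float(np.sort(np.asarray(hs))[::-1][:3].mean())
                for _, hs in per_cell_heights
            ]
            ref = float(np.mean(refs))
            new_thr = fraction * ref
            result = DetectionThreshold(
                reference_100pct=ref, threshold=new_thr, cohort_id=cohort_id,
                n_pooled_peaks=len(pooled), fraction=fraction,
            )
        else:
            result = threshold_from_peak_heights(
                pooled, fraction=fraction, cohort_id=cohort_id
            )
            new_thr = result.threshold
        signature = tuple(sorted((cid, tuple(sorted(hs))) for cid, hs in per_cell_heights))
        if signature == prev_signature or abs(new_thr - thr) < 1e-12:
            thr = new_thr
            break
        prev_signature = signature
        thr = new_thr
    return result


def oscillation_metrics(
    dff: DffTrace,
    peaks: list[Peak],
    observed_duration_s: float | None = None,
) -> OscillationMetrics:
    """Per-cell summary: frequency = n_peaks / (duration/60); mean dF/F0 =
    arithmetic mean of all (valid) samples.  The duration defaults to the
    cell's observed span (first to last valid sample, inclusive of one frame
    interval)."""
    if observed_duration_s is None:
        valid = np.nonzero(np.isfinite(dff.dff))[0]
        if valid.size == 0:
            raise ValueError("trace has no valid samples")
        observed_duration_s = float(
            dff.t_s[valid[-1]] - dff.t_s[valid[0]] + dff.frame_interval_s
        )
    if not (observed_duration_s > 0):
        raise ValueError("observed duration must be > 0")
    n = len(peaks)
    return OscillationMetrics(
        cell_id=dff.cell_id,
        n_peaks=n,
        frequency_per_min=n / (observed_duration_s / 60.0),
        mean_dff=float(np.nanmean(dff.dff)),
        observed_duration_s=float(observed_duration_s),
        oscillating=n >= 1,
    )
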