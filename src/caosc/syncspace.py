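"""Tip-stalk synchrony and spatial summaries.

Synchrony: a Ca2+ rise in one cell counts as synchronous when some rise in
the partner cell falls within a 10-s window (absolute lag, boundary
inclusive -- the directional "within 10 s late behind" criterion applied in
both directions).  A high asynchronous fraction argues against intercellular
Ca2+ waves as the source of the oscillations.

Space: the dorsal aorta between two somite boundaries is split into three
equal thirds (Regions 1-3) by the nucleus position at the first frame, and
oscillating budding cells are counted per somite boundary (categories 1, 2,
3+ oscillating cells) or per ISV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SynchronyResult",
    "RegionAssignment",
    "BoundaryCount",
    "classify_synchrony",
    "assign_region",
    "count_oscillating_cells",
]

DEFAULT_SYNC_WINDOW_S = 10.0
CATEGORY_LABELS = ("1", "2", "3+")


@dataclass
class SynchronyResult:
    cell_a: object
    cell_b: object
    labels_a: np.ndarray  # bool per rise of A: synchronous?
    labels_b: np.ndarray
    window_s: float = DEFAULT_SYNC_WINDOW_S

    @property
    def pct_synchronous_a(self) -> float:
        return 100.0 * self.labels_a.mean() if len(self.labels_a) else np.nan

    @property
    def pct_synchronous_b(self) -> float:
        return 100.0 * self.labels_b.mean() if len(self.labels_b) else np.nan

    @property
    def pct_asynchronous_a(self) -> float:
        return 100.0 - self.pct_synchronous_a

    @property
    def pct_asynchronous_b(self) -> float:
        return 100.0 - self.pct_synchronous_b


def classify_synchrony(
    rises_a,
    rises_b,
    window_s: float = DEFAULT_SYNC_WINDOW_S,
    cell_a: object = "A",
    cell_b: object = "B",
) -> SynchronyResult:
    """Label every rise of each cell as synchronous or asynchronous.

    A rise at t_A is synchronous iff some partner rise t_B satisfies
    |t_B - t_A| <= window_s (any-match semantics; a rise may match several
    partner rises).  Cells with no rises get NaN percentages, not 0.
    """
    a = np.asarray(list(rises_a), dtype=float)
    b = np.asarray(list(rises_b), dtype=float)
    if np.any(np.diff(a) < 0) or np.any(np.diff(b) < 0):
        raise ValueError("rise times must be sorted ascending")
    if len(a) and len(b):
        lag = np.abs(a[:, None] - b[None, :])
        labels_a = (lag <= window_s).any(axis=1)
        labels_b = (lag <= window_s).any(axis=0)
    else:
        labels_a = np.zeros(len(a), dtype=bool)
        labels_b = np.zeros(len(b), dtype=bool)
    return SynchronyResult(
        cell_a=cell_a, cell_b=cell_b,
        labels_a=labels_a, labels_b=labels_b, window_s=window_s,
    )


@dataclass
class RegionAssignment:
    cell_id: object
    region: int | None  # 1..3, or None when outside all boundary intervals
    left_x_um: float = np.nan
    right_x_um: float = np.nan
    nucleus_x_um: float = np.nan


def assign_region(
    nucleus_x_at_t0_um: float,
    somite_boundaries_x_um,
    cell_id: object = None,
) -> RegionAssignment:
    """Assign a cell to Region 1-3 of its enclosing boundary interval.

    The interval [left, right) between consecutive somite boundaries is split
    into three equal half-open thirds; the region is the index of the third
    containing the nucleus x at the first frame.  The very last boundary is
    treated as belonging to the final interval so that the covered range
    [first, last] is fully partitioned.  A nucleus outside all intervals is
    unassigned with a warning.
    """
    x = float(nucleus_x_at_t0_um)
    b = np.asarray(somite_boundaries_x_um, dtype=float)
    if b.ndim != 1 or len(b) < 2:
        raise ValueError("need at least two sorted somite boundaries")
    if np.any(np.diff(b) <= 0):
        raise ValueError("somite boundaries must be sorted strictly ascending")
    if x < b[0] or x > b[-1]:
        warnings.warn(
            f"nucleus x={x} outside boundary range [{b[0]}, {b[-1]}]; unassigned",
            stacklevel=2,
        )
        return RegionAssignment(cell_id=cell_id, region=None, nucleus_x_um=x)
    i = int(np.searchsorted(b, x, side="right")) - 1
    if i == len(b) - 1:  # x exactly at the last boundary
        i -= 1
    left, right = b[i], b[i + 1]
    third = (right - left) / 3.0
    region = min(2, int((x - left) // third)) + 1
    return RegionAssignment(
        cell_id=cell_id, region=region,
        left_x_um=float(left), right_x_um=float(right), nucleus_x_um=x,
    )


@dataclass
class BoundaryCount:
    boundary_x_um: float
    n_oscillating: int
    category: str  # "1", "2", "3+"


def count_oscillating_cells(
    cells: pd.DataFrame,
    somite_boundaries_x_um,
    mode: str = "per_boundary",
    side: str | None = None,
) -> tuple[list[BoundaryCount], dict[str, float]]:
    """Count oscillating budding cells at each somite boundary.

    ``cells`` needs columns cell_id, x_um (nucleus x at the first frame),
    oscillating (bool), budding (bool), side, following_tip.  Each
    oscillating budding cell is assigned to its nearest boundary by |dx|
    (ties to the anterior boundary); with ``mode='per_isv'`` only cells
    following a tip cell are counted.  Returns per-boundary counts for
    boundaries with at least one oscillating cell and the percentage of
    those boundaries in each category (1, 2, 3+ cells).
    """
    b = np.asarray(somite_boundaries_x_um, dtype=float)
    if b.size == 0:
        raise ValueError("no somite boundaries given")
    if mode not in ("per_boundary", "per_isv"):
        raise ValueError("mode must be 'per_boundary' or 'per_isv'")
    sel = cells
    if side is not None:
        sel = sel[sel["side"] == side]
    sel = sel[sel["budding"].astype(bool) & sel["oscillating"].astype(bool)]
    if mode == "per_isv":
        sel = sel[sel["following_tip"].astype(bool)]
    counts = np.zeros(len(b), dtype=int)
    for x in sel["x_um"].to_numpy(dtype=float):
        d = np.abs(b - x)
        counts[int(np.argmin(d))] += 1  # argmin ties -> lowest index (anterior)
    results = [
        BoundaryCount(
            boundary_x_um=float(b[i]),
            n_oscillating=int(c),
            category="3+" if c >= 3 else str(int(c)),
        )
        for i, c in enumerate(counts)
        if c >= 1
    ]
    n_active = len(results)
    percentages = {
        label: (
            100.0 * sum(1 for r in results if r.category == label) / n_active
            if n_active
            else np.nan
        )
        for label in CATEGORY_LABELS
    }
    return results, percentages
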