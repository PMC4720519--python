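"""Independent brute-force oracles used by the tests.

Each function here re-derives a quantity by exhaustive enumeration or a
direct transliteration of its mathematical definition, deliberately sharing
no code with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_max_in_sphere(volume, center_um, radius_um, voxel_size_zyx_um):
    """Triple-loop scan over every voxel; max of values whose centre is
    within the sphere (closed ball)."""
    sz, sy, sx = voxel_size_zyx_um
    cx, cy, cz = center_um
    best = None
    nz, ny, nx = volume.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                dz = k * sz - cz
                dy = j * sy - cy
                dx = i * sx - cx
                d2 = (dz * dz + dy * dy) + dx * dx
                if d2 <= radius_um * radius_um:
                    v = volume[k, j, i]
                    if best is None or v > best:
                        best = v
    return np.nan if best is None else float(best)


def brute_local_maxima(x):
    """Local maxima with plateau handling: a run of equal samples strictly
    above both neighbours is one peak at the plateau midpoint (floor).
    Signal edges are never peaks.  Returns apex indices."""
    peaks = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def brute_prominence(x, apex):
    """Prominence: apex height minus the higher of the two interval minima,
    where each interval runs from the apex to the nearest strictly higher
    sample on that side (or the signal edge)."""
    h = x[apex]
    left_min = h
    for i in range(apex - 1, -1, -1):
        if x[i] > h:
            break
        left_min = min(left_min, x[i])
    right_min = h
    for i in range(apex + 1, len(x)):
        if x[i] > h:
            break
        right_min = min(right_min, x[i])
    return h - max(left_min, right_min)


def brute_detect_peaks(x, t_s, threshold, min_separation_s):
    """Exhaustive peak detection: local maxima (plateau midpoint), apex
    height >= threshold, prominence >= threshold, then greedy pruning by
    descending apex height (ties: earlier apex) removing any apex closer
    than min_separation_s to a kept one.  Handles NaN gaps by splitting.
    Returns sorted apex indices."""
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    candidates = []
    start = None
    for i in range(len(x) + 1):
        inside = i < len(x) and finite[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            seg = x[start:i]
            for apex in brute_local_maxima(seg):
                h = seg[apex]
                if h >= threshold and brute_prominence(seg, apex) >= threshold:
                    candidates.append((start + apex, h))
            start = None
    kept = []
    for apex, h in sorted(candidates, key=lambda c: (-c[1], c[0])):
        if all(abs(t_s[apex] - t_s[k]) >= min_separation_s for k in kept):
            kept.append(apex)
    return sorted(kept)


def brute_synchrony_labels(rises_a, rises_b, window_s):
    """Per-rise synchrony of A against B by exhaustive pairwise lags."""
    labels = []
    for ta in rises_a:
        labels.append(any(abs(tb - ta) <= window_s for tb in rises_b))
    return labels


def brute_assign_region(x, boundaries):
    """Region 1-3 by exhaustive scan over every interval and third."""
    b = list(boundaries)
    for i in range(len(b) - 1):
        left, right = b[i], b[i + 1]
        last_interval = i == len(b) - 2
        if left <= x < right or (last_interval and x == right):
            third = (right - left) / 3.0
            for r in range(3):
                lo = left + r * third
                hi = left + (r + 1) * third
                if lo <= x < hi or (r == 2 and x == hi):
                    return r + 1, left, right
    return None, None, None


def brute_min_cost_assignment(cost):
    """Exhaustive minimum-cost assignment over all permutations (small n)."""
    from itertools import permutations

    n_rows, n_cols = cost.shape
    best, best_perm = math.inf, None
    k = min(n_rows, n_cols)
    rows = range(n_rows)
    for row_sel in permutations(rows, k):
        total = sum(cost[r, c] for c, r in enumerate(row_sel))
        if total < best:
            best, best_perm = total, row_sel
    return best, best_perm


def student_t_p_value(a, b):
    """Two-sided equal-variance two-sample t-test p-value by explicit
    formulas: pooled variance, t statistic, and numerical integration of the
    t density written out with math.gamma."""
    from scipy.integrate import quad

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))

    def pdf(u):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = quad(pdf, abs(t), math.inf)
    return 2.0 * tail
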