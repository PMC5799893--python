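"""Independent brute-force oracles for segmentation and morphometry.

Everything here is deliberately naive — per-pixel loops, flood fills,
exhaustive searches — and shares no code path with the package, so
agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_labels(mask: np.ndarray) -> np.ndarray:
    """8-connected component labels by BFS, 1..n in raster order of first pixel."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                queue = deque([(i, j)])
                labels[i, j] = nxt
                while queue:
                    y, x = queue.popleft()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx_ = y + dy, x + dx
                            if (
                                0 <= ny < h
                                and 0 <= nx_ < w
                                and mask[ny, nx_]
                                and labels[ny, nx_] == 0
                            ):
                                labels[ny, nx_] = nxt
                                queue.append((ny, nx_))
    return labels


def fill_holes_bruteforce(labels: np.ndarray) -> np.ndarray:
    """Fill enclosed background: BFS outside-reachable background (4-conn),
    everything else background gets its enclosing particle's label."""
    labels = np.asarray(labels).copy()
    h, w = labels.shape
    outside = np.zeros((h, w), dtype=bool)
    queue = deque()
    for i in range(h):
        for j in (0, w - 1):
            if labels[i, j] == 0 and not outside[i, j]:
                outside[i, j] = True
                queue.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if labels[i, j] == 0 and not outside[i, j]:
                outside[i, j] = True
                queue.append((i, j))
    while queue:
        y, x = queue.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] == 0 and not outside[ny, nx]:
                outside[ny, nx] = True
                queue.append((ny, nx))
    holes = (labels == 0) & ~outside
    # assign each hole pixel the majority label among 8-neighbouring particles,
    # growing until no hole pixel remains
    while holes.any():
        progressed = False
        for i, j in zip(*np.nonzero(holes)):
            neigh = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = i + dy, j + dx
                    if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] > 0:
                        neigh.append(labels[ny, nx])
            if neigh:
                labels[i, j] = max(set(neigh), key=neigh.count)
                holes[i, j] = False
                progressed = True
        if not progressed:  # isolated background with no particle neighbour
            break
    return labels


def area_bruteforce(labels: np.ndarray, lab: int) -> int:
    return int(sum(1 for v in labels.ravel() if v == lab))


def perimeter_bruteforce(labels: np.ndarray, lab: int) -> int:
    """Pixels of the particle with a 4-neighbour outside it (edge = outside)."""
    h, w = labels.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if labels[i, j] != lab:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = i + dy, j + dx
                if not (0 <= ny < h and 0 <= nx < w) or labels[ny, nx] != lab:
                    count += 1
                    break
    return count


def _boundary_points(labels: np.ndarray, lab: int) -> np.ndarray:
    h, w = labels.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if labels[i, j] != lab:
                continue
            border = False
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = i + dy, j + dx
                if not (0 <= ny < h and 0 <= nx < w) or labels[ny, nx] != lab:
                    border = True
                    break
            if border:
                pts.append((i, j))
    return np.asarray(pts, dtype=float)


def feret_bruteforce(labels: np.ndarray, lab: int) -> tuple[float, float]:
    """(max Feret, min width) by exhaustive sweep over boundary-pixel pairs.

    Extremes of any projection are attained at boundary pixels, and the
    minimal width is flush with a segment between two boundary pixels, so
    scanning all boundary pairs is exact.
    """
    pts = _boundary_points(labels, lab)
    n = len(pts)
    if n == 1:
        return 0.0, 0.0
    max_feret = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            max_feret = max(max_feret, float(np.linalg.norm(pts[i] - pts[j])))
    min_width = math.inf
    for i in range(n):
        for j in range(i + 1, n):
            d = pts[j] - pts[i]
            norm = math.hypot(d[0], d[1])
            if norm == 0:
                continue
            normal = np.array([-d[1], d[0]]) / norm
            proj = pts @ normal
            min_width = min(min_width, float(proj.max() - proj.min()))
    if not math.isfinite(min_width):
        min_width = 0.0
    return max_feret, min_width


def roundness_bruteforce(labels: np.ndarray, lab: int) -> float:
    if area_bruteforce(labels, lab) == 1:
        return 1.0
    max_feret, min_width = feret_bruteforce(labels, lab)
    return max_feret / max(1.0, min_width)


def isodata_fixed_points(hist: np.ndarray) -> list[int]:
    """All t in [0, 255] that are fixed points of the clamped intermeans rule."""
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(256)
    nonzero = np.flatnonzero(hist)
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    fixed = []
    for t in range(256):
        low = hist[: t + 1]
        high = hist[t + 1 :]
        if low.sum() == 0 or high.sum() == 0:
            continue
        low_mean = (low * levels[: t + 1]).sum() / low.sum()
        high_mean = (high * levels[t + 1 :]).sum() / high.sum()
        t_next = int((low_mean + high_mean) // 2)
        t_next = min(max(t_next, lo), hi - 1)
        if t_next == t:
            fixed.append(t)
    return fixed


def km_product_limit(times, events):
    """Hand-rolled product-limit estimator: [(time, S(t))] at event times."""
    order = np.argsort(times)
    times = np.asarray(times, float)[order]
    events = np.asarray(events, int)[order]
    n = len(times)
    s = 1.0
    out = []
    at_risk = n
    i = 0
    while i < n:
        t = times[i]
        d = 0
        c = 0
        while i < n and times[i] == t:
            d += events[i]
            c += 1 - events[i]
            i += 1
        if d:
            s *= 1.0 - d / at_risk
            out.append((t, s))
        at_risk -= d + c
    return out
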