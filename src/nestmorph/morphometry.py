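"""Per-particle shape descriptors and spot-level feature aggregation.

Conventions (all in pixel units, chosen for internal consistency and exact
testability rather than mimicry of any one tool):

* area — number of pixels carrying the particle's label (holes are filled
  upstream, so lumina count toward area);
* perimeter — number of particle pixels with at least one 4-neighbour
  outside the particle (the one-pixel-thick border; the image edge counts
  as outside; a pixel merely diagonal to background is not border);
* circularity — 4πA/P², capped at 1 (small discrete particles exceed 1
  under the raw formula); 1 means a smooth, compact outline;
* roundness — max Feret diameter / min Feret width over pixel centres
  (rotating calipers on the convex hull), with the minimum width floored at
  1 px; ≥ 1, larger = more elongated.  An ImageJ-style alternative
  4A/(π·major²) in (0, 1] is available via ``convention='imagej'`` — note
  the two are reciprocally oriented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .segmentation import ParticleMap

ROUNDNESS_CONVENTIONS = ("feret_ratio", "imagej")


@dataclass
class NestRecord:
    """Shape descriptors of one tumour nest (connected particle)."""

    label: int
    area: int
    perimeter: int
    circularity: float
    roundness: float


@dataclass
class SpotFeatures:
    """The seven spot-level microarchitectural features.

    Means are NaN when the spot has no nests (the spot is flagged, not
    dropped).
    """

    n_nests: int
    total_area: int
    mean_area: float
    total_perimeter: int
    mean_perimeter: float
    mean_circularity: float
    mean_roundness: float


def _particle_mask(pmap: ParticleMap, label: int) -> np.ndarray:
    if not 1 <= label <= pmap.n_particles:
        raise KeyError(f"no particle with label {label} (1..{pmap.n_particles})")
    return pmap.labels == label


def particle_area(pmap: ParticleMap, label: int) -> int:
    """Pixel count of one particle (holes already filled upstream)."""
    return int(_particle_mask(pmap, label).sum())


def _border_mask(mask: np.ndarray) -> np.ndarray:
    """Pixels of ``mask`` with at least one 4-neighbour outside it."""
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return mask & ~interior


def particle_perimeter(pmap: ParticleMap, label: int) -> int:
    """Border-pixel count: particle pixels 4-adjacent to outside."""
    return int(_border_mask(_particle_mask(pmap, label)).sum())


def particle_circularity(area: float, perimeter: float, cap: bool = True) -> float:
    """Circularity 4πA/P², capped at 1 unless ``cap=False`` (diagnostics)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    if area <= 0:
        raise ValueError("area must be positive")
    raw = 4.0 * math.pi * area / (perimeter * perimeter)
    return min(1.0, raw) if cap else raw


def _feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """(max Feret diameter, min Feret width) of a set of pixel centres.

    Rotating calipers on the convex hull: the maximum Feret is the hull
    diameter; the minimum width is attained flush with a hull edge.
    Degenerate (collinear) sets have width 0.
    """
    if len(points) == 1:
        return 0.0, 0.0
    pts = points.astype(float)
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear points
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        return float(d.max()), 0.0
    diff = hull[:, None, :] - hull[None, :, :]
    max_feret = float(np.sqrt((diff**2).sum(-1)).max())
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.linalg.norm(edges, axis=1)
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    proj = normals @ hull.T  # (n_edges, n_vertices)
    widths = proj.max(axis=1) - proj.min(axis=1)
    return max_feret, float(widths.min())


def particle_roundness(
    pmap: ParticleMap, label: int, convention: str = "feret_ratio"
) -> float:
    """Elongation of one particle.

    'feret_ratio' (default): longest / shortest Feret diameter with a 1-px
    floor on the shortest; a single pixel has roundness 1.  'imagej':
    4·area/(π·major²) where major is the max Feret diameter.
    """
    if convention not in ROUNDNESS_CONVENTIONS:
        raise ValueError(f"unknown roundness convention: {convention!r}")
    mask = _particle_mask(pmap, label)
    points = np.argwhere(mask)
    max_feret, min_width = _feret_diameters(points)
    if convention == "feret_ratio":
        if len(points) == 1:
            return 1.0
        return max_feret / max(1.0, min_width)
    if max_feret == 0.0:
        return 1.0
    return min(1.0, 4.0 * mask.sum() / (math.pi * max_feret**2))


def nest_records(
    pmap: ParticleMap,
    cap_circularity: bool = True,
    roundness_convention: str = "feret_ratio",
) -> list[NestRecord]:
    """Per-particle records for every particle in the map.

    Areas and perimeters are computed for all labels in one vectorized pass;
    roundness per particle via rotating calipers.
    """
    n = pmap.n_particles
    if n == 0:
        return []
    labels = pmap.labels
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    padded = np.pad(labels, 1, constant_values=-1)
    same_all4 = (
        (padded[:-2, 1:-1] == labels)
        & (padded[2:, 1:-1] == labels)
        & (padded[1:-1, :-2] == labels)
        & (padded[1:-1, 2:] == labels)
    )
    border = (labels > 0) & ~same_all4
    perims = np.bincount(labels[border], minlength=n + 1)
    records = []
    for lab in range(1, n + 1):
        a, p = int(areas[lab]), int(perims[lab])
        records.append(
            NestRecord(
                label=lab,
                area=a,
                perimeter=p,
                circularity=particle_circularity(a, p, cap=cap_circularity),
                roundness=particle_roundness(pmap, lab, roundness_convention),
            )
        )
    return records


def spot_features(
    pmap: ParticleMap | list[NestRecord],
    cap_circularity: bool = True,
    roundness_convention: str = "feret_ratio",
) -> SpotFeatures:
    """Aggregate per-particle records into the spot-level feature vector."""
    if isinstance(pmap, ParticleMap):
        records = nest_records(pmap, cap_circularity, roundness_convention)
    else:
        records = pmap
    n = len(records)
    if n == 0:
        return SpotFeatures(0, 0, float("nan"), 0, float("nan"), float("nan"), float("nan"))
    total_area = sum(r.area for r in records)
    total_perim = sum(r.perimeter for r in records)
    return SpotFeatures(
        n_nests=n,
        total_area=total_area,
        mean_area=total_area / n,
        total_perimeter=total_perim,
        mean_perimeter=total_perim / n,
        mean_circularity=sum(r.circularity for r in records) / n,
        mean_roundness=sum(r.roundness for r in records) / n,
    )
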