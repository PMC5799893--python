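"""Spot segmentation: blue channel → automatic threshold → particles.

The segmentation chain mirrors the classic ImageJ particle-analysis recipe
for DAB-stained tumour on a haematoxylin counterstain: split RGB, keep the
blue channel (DAB brown is dark in blue, counterstain pale), threshold the
histogram automatically, binarize with dark pixels as foreground, label
8-connected components, fill internal holes (lumina belong to their nest),
and discard particles smaller than ``min_area`` square pixels (default 30,
slightly above a single cell).

Connectivity convention: foreground components are 8-connected, background
regions (for hole detection) 4-connected — the complementary pair avoids
topological paradoxes.  Holes are filled *before* the size filter, so the
filter acts on filled areas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label

from .spot_io import QCFlags, SpotImage, logger

# 4- and 8-neighbourhood structuring elements
_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


class DegenerateHistogramError(ValueError):
    """Histogram has a single grey level; no threshold exists (weak staining)."""


class PlacementError(RuntimeError):
    """Raised by callers when a spot cannot be processed at all."""


@dataclass
class SegmentationConfig:
    """Tunable knobs of the segmentation chain.

    threshold_method: 'isodata' (iterated intermeans, the ImageJ default) or
        'otsu'.
    min_area: particle size cutoff in px²; particles with filled area below
        it are discarded (kept if area ≥ min_area).
    min_tissue_fraction: spots with less tissue than this fraction are
        excluded at QC.
    background_cutoff: a pixel counts as tissue when min(R, G, B) is below
        this intensity; explicit surrogate for a visual tissue check.
    """

    threshold_method: Literal["isodata", "otsu"] = "isodata"
    min_area: int = 30
    min_tissue_fraction: float = 0.5
    background_cutoff: int = 220

    # foreground connectivity is fixed at 8 (ImageJ convention); documented,
    # not configurable
    connectivity: int = 8


@dataclass
class GrayImage:
    """Single-channel 8-bit image with a note of which channel it came from."""

    pixels: np.ndarray  # (H, W) uint8
    provenance: str = "blue"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D intensity grid")


@dataclass
class BinaryMask:
    """Foreground/background mask with the threshold that produced it."""

    pixels: np.ndarray  # (H, W) bool, True = foreground
    threshold_used: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)


@dataclass
class ParticleMap:
    """Labelled particles: 0 = background, labels 1..n_particles consecutive."""

    labels: np.ndarray  # (H, W) int32
    n_particles: int
    min_area_applied: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)


def extract_blue_channel(img: SpotImage) -> GrayImage:
    """Keep the blue channel, discard red and green."""
    return GrayImage(pixels=img.pixels[:, :, 2], provenance="blue")


def _isodata_threshold(hist: np.ndarray) -> int:
    """Least fixed point of the iterated intermeans rule on a 256-bin histogram.

    t ← floor((mean(levels ≤ t) + mean(levels > t)) / 2), iterated upward
    from the darkest occupied level — the classic iterative-intermeans
    implementation scans up from the histogram minimum, which selects the
    dark/pale split even when the pale side has several close modes (e.g.
    counterstain next to bare glass).  The step map is monotone, so the
    iteration increases to the least fixed point; both classes stay
    non-empty because t is clamped to [min level, max level − 1].
    """
    levels = np.arange(256)
    nonzero = np.flatnonzero(hist)
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    if lo == hi:
        raise DegenerateHistogramError(
            f"constant image (single grey level {lo}); cannot threshold"
        )
    total = hist.sum()
    csum = np.cumsum(hist)
    cwsum = np.cumsum(hist * levels)

    def step(t: int) -> int:
        low_mean = cwsum[t] / csum[t]
        high_mean = (cwsum[255] - cwsum[t]) / (total - csum[t])
        t_next = int((low_mean + high_mean) // 2)
        return min(max(t_next, lo), hi - 1)

    t = lo
    while True:
        t_next = step(t)
        if t_next == t:
            return t
        t = t_next


def auto_threshold(
    gray: GrayImage | np.ndarray, method: Literal["isodata", "otsu"] = "isodata"
) -> int:
    """Automatic histogram threshold on an 8-bit image.

    Returns an intensity t in [0, 255]; downstream, foreground = pixels ≤ t.
    Raises :class:`DegenerateHistogramError` on a constant image (the caller
    marks the spot as weak staining).
    """
    pixels = gray.pixels if isinstance(gray, GrayImage) else np.asarray(gray)
    if pixels.size == 0:
        raise ValueError("empty image")
    hist = np.bincount(pixels.ravel().astype(np.uint8), minlength=256)
    if method == "isodata":
        return _isodata_threshold(hist)
    if method == "otsu":
        if np.count_nonzero(hist) < 2:
            raise DegenerateHistogramError("constant image; cannot threshold")
        return int(threshold_otsu(hist=(hist, np.arange(256))))
    raise ValueError(f"unknown threshold method: {method!r}")


def binarize(gray: GrayImage | np.ndarray, t: int) -> BinaryMask:
    """Dark-object binarization: foreground iff intensity ≤ t."""
    if not 0 <= t <= 255:
        raise ValueError(f"threshold {t} outside [0, 255]")
    pixels = gray.pixels if isinstance(gray, GrayImage) else np.asarray(gray)
    return BinaryMask(pixels=pixels <= t, threshold_used=int(t))


def _relabel_raster_order(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels 1..n by raster-scan order of each component's first pixel."""
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    keep = ids > 0
    ids, first = ids[keep], first[keep]
    order = ids[np.argsort(first)]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, len(order) + 1, dtype=np.int32)
    return lut[labels], len(order)


def label_particles(mask: BinaryMask | np.ndarray) -> ParticleMap:
    """Label maximal 8-connected foreground components.

    Labels run 1..n in raster-scan order of each component's first pixel.
    """
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    raw = _sk_label(pixels, connectivity=2)
    labels, n = _relabel_raster_order(raw)
    return ParticleMap(labels=labels, n_particles=n, min_area_applied=None)


def fill_holes(pmap: ParticleMap) -> ParticleMap:
    """Assign enclosed background regions the label of their enclosing particle.

    A hole is a 4-connected background region not 4-connected to the image
    border.  Areas never decrease; the operation is idempotent.  When a hole
    borders several particles (possible only for oddly interleaved shapes)
    it takes the majority neighbouring label.
    """
    labels = pmap.labels.copy()
    background = labels == 0
    bg_labels, n_bg = ndimage.label(background, structure=_STRUCT4)
    if n_bg == 0:
        return ParticleMap(labels, pmap.n_particles, pmap.min_area_applied)
    border_ids = np.unique(
        np.concatenate(
            [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
        )
    )
    hole_ids = np.setdiff1d(np.arange(1, n_bg + 1), border_ids)
    if hole_ids.size:
        slices = ndimage.find_objects(bg_labels)
        for hid in hole_ids:
            sl = slices[hid - 1]
            pad = (
                slice(max(sl[0].start - 1, 0), min(sl[0].stop + 1, labels.shape[0])),
                slice(max(sl[1].start - 1, 0), min(sl[1].stop + 1, labels.shape[1])),
            )
            region = bg_labels[pad] == hid
            rim = ndimage.binary_dilation(region, structure=_STRUCT8) & ~region
            rim_labels = labels[pad][rim]
            rim_labels = rim_labels[rim_labels > 0]
            if rim_labels.size:
                fill_with = np.bincount(rim_labels).argmax()
                sub = labels[pad]
                sub[region] = fill_with
    return ParticleMap(labels, pmap.n_particles, pmap.min_area_applied)


def filter_particles(pmap: ParticleMap, min_area: int = 30) -> ParticleMap:
    """Discard particles with (filled) area < min_area; relabel consecutively.

    The boundary is inclusive: area ≥ min_area is kept.  Idempotent.
    """
    counts = np.bincount(pmap.labels.ravel(), minlength=pmap.n_particles + 1)
    keep = np.flatnonzero(counts >= min_area)
    keep = keep[keep > 0]
    lut = np.zeros(pmap.n_particles + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return ParticleMap(
        labels=lut[pmap.labels], n_particles=len(keep), min_area_applied=int(min_area)
    )


def qc_spot(img: SpotImage, config: SegmentationConfig | None = None) -> QCFlags:
    """Tissue-fraction QC: excluded when less than ``min_tissue_fraction`` of
    pixels look like tissue (min(R,G,B) below the background cutoff).

    The boundary is inclusive: exactly the minimum fraction is retained.
    """
    config = config or SegmentationConfig()
    tissue = img.pixels.min(axis=2) < config.background_cutoff
    frac = float(tissue.mean())
    if frac < config.min_tissue_fraction:
        return QCFlags(
            tissue_fraction=frac,
            excluded=True,
            reason=f"tissue fraction {frac:.3f} < {config.min_tissue_fraction}",
        )
    return QCFlags(tissue_fraction=frac)


def segment_spot(
    img: SpotImage, config: SegmentationConfig | None = None
) -> ParticleMap:
    """Full chain: blue channel → threshold → binarize → label → fill → filter.

    Raises :class:`DegenerateHistogramError` when thresholding fails (the
    caller records the spot as a weak-staining QC exclusion).
    """
    config = config or SegmentationConfig()
    gray = extract_blue_channel(img)
    t = auto_threshold(gray, method=config.threshold_method)
    mask = binarize(gray, t)
    pmap = label_particles(mask)
    pmap = fill_holes(pmap)
    pmap = filter_particles(pmap, min_area=config.min_area)
    logger.debug(
        "spot %s: threshold=%d, %d particles after %d px² filter",
        img.spot_id,
        t,
        pmap.n_particles,
        config.min_area,
    )
    return pmap
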