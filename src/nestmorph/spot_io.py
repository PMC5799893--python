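"""Reading and writing spot images, masks, and clinical/feature tables.

Images come in as TIFF/PNG/JPEG rasters (one tissue-microarray spot per
file), decoded to 8-bit RGB exactly as stored — no recompression, no colour
management.  JPEG is accepted because acquisition pipelines commonly export
it, but lossless formats are preferred for anything downstream of
acquisition.  Binary masks go out as single-channel PNG with background 0
and foreground 255 (foreground bright for visibility).

Tables are UTF-8 CSV with a mandatory header.  Booleans are encoded 0/1 and
missing values as empty cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger("nestmorph")

SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


class SpotIOError(IOError):
    """Unreadable or truncated image/table file."""


class FormatError(SpotIOError):
    """File decodes but is not 8-bit RGB/grayscale raster data."""


class ValidationError(ValueError):
    """Table content violates the schema (e.g. duplicate spot ids)."""


@dataclass
class QCFlags:
    """Per-spot quality-control outcome.

    tissue_fraction is the fraction of pixels darker than the background
    cutoff in at least one channel; spots with less than half tissue are
    excluded, as are spots whose staining is too weak to threshold.
    """

    tissue_fraction: float = float("nan")
    weak_staining: bool = False
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.reason:
            raise ValueError("excluded spots must carry a non-empty reason")


@dataclass
class SpotImage:
    """One TMA spot: an 8-bit RGB pixel grid plus identifier and QC flags."""

    spot_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    qc: QCFlags = field(default_factory=QCFlags)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel (uint8)")
        if self.height < 1 or self.width < 1:
            raise ValueError("image must be at least 1x1")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def read_spot_image(path: str | Path, spot_id: str | None = None) -> SpotImage:
    """Read a TIFF/PNG/JPEG raster into a :class:`SpotImage`.

    Grayscale input is expanded to three equal RGB channels (with a logged
    warning); an alpha channel, if present, is dropped.  Raises
    :class:`SpotIOError` for unreadable/truncated files and
    :class:`FormatError` for unsupported bit depths or modes.
    """
    path = Path(path)
    if not path.is_file():
        raise SpotIOError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("I", "I;16", "I;16B", "F"):
                raise FormatError(
                    f"{path}: unsupported bit depth (mode {mode}); 8-bit required"
                )
            if mode in ("L", "1", "P"):
                logger.warning(
                    "%s: grayscale/palette image expanded to equal RGB channels", path
                )
                im = im.convert("RGB")
            elif mode == "RGBA":
                im = im.convert("RGB")
            elif mode != "RGB":
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except FormatError:
        raise
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise SpotIOError(f"cannot read image {path}: {exc}") from exc
    return SpotImage(spot_id=spot_id or path.stem, pixels=arr)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel PNG (0 background, 255 foreground)."""
    mask = np.asarray(mask)
    out = np.where(mask.astype(bool), 255, 0).astype(np.uint8)
    Image.fromarray(out, mode="L").save(Path(path), format="PNG")


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a mask PNG back to a boolean array (nonzero = foreground)."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


# --- tables -----------------------------------------------------------------

FEATURE_COLUMNS = [
    "spot_id",
    "patient_id",
    "n_nests",
    "total_area",
    "mean_area",
    "total_perimeter",
    "mean_perimeter",
    "mean_circularity",
    "mean_roundness",
    "tissue_fraction",
    "weak_staining",
    "excluded",
    "reason",
]

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "grade",
    "tumour_size",
    "er",
    "her2",
    "node_positive",
    "chemo",
    "bcss_time",
    "bcss_event",
    "ttdm_time",
    "ttdm_event",
]

_BOOL_COLUMNS = {
    "weak_staining",
    "excluded",
    "er",
    "her2",
    "node_positive",
    "chemo",
    "bcss_event",
    "ttdm_event",
}


def _encode_bools(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in _BOOL_COLUMNS:
            vals = out[col]
            out[col] = vals.map(lambda v: "" if pd.isna(v) else str(int(bool(v))))
    return out


def write_feature_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write per-spot features (one row per spot) to CSV with fixed column order.

    Raises :class:`ValidationError` on duplicate spot ids.  Integer fields
    round-trip losslessly.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty:
        df = pd.DataFrame(columns=FEATURE_COLUMNS)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    for c in missing:
        df[c] = "" if c == "reason" else np.nan
    if df["spot_id"].duplicated().any():
        dupes = sorted(df.loc[df["spot_id"].duplicated(), "spot_id"].unique())
        raise ValidationError(f"duplicate spot_id values: {dupes}")
    df = df[FEATURE_COLUMNS]
    _encode_bools(df).to_csv(Path(path), index=False, encoding="utf-8")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a per-spot feature CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(Path(path), encoding="utf-8")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table {path} missing columns: {missing}")
    for col in ("n_nests", "total_area", "total_perimeter"):
        if df[col].notna().all() and len(df):
            df[col] = df[col].astype(int)
    for col in _BOOL_COLUMNS & set(df.columns):
        df[col] = df[col].astype("Int64")
    df["reason"] = df["reason"].fillna("").astype(str)
    return df


def write_patient_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a clinical table to CSV (booleans as 0/1, missing as empty)."""
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"patient table missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient_id values")
    out = df[PATIENT_COLUMNS + [c for c in df.columns if c not in PATIENT_COLUMNS]]
    _encode_bools(out).to_csv(Path(path), index=False, encoding="utf-8")


def read_patient_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical table.

    Times must be non-negative and grade in {1, 2, 3}; rows with missing
    outcomes are kept (downstream fits drop them per analysis, with the
    count logged) — never silently dropped here.
    """
    df = pd.read_csv(Path(path), encoding="utf-8")
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"patient table {path} missing columns: {missing}")
    for col in _BOOL_COLUMNS & set(df.columns):
        df[col] = df[col].astype("Int64")
    grades = df["grade"].dropna()
    if not grades.isin([1, 2, 3]).all():
        raise ValidationError("grade must be 1, 2 or 3")
    for col in ("bcss_time", "ttdm_time"):
        times = df[col].dropna()
        if (times < 0).any():
            raise ValidationError(f"{col} contains negative times")
    n_missing_outcome = int(
        df[["node_positive", "bcss_time", "ttdm_time"]].isna().any(axis=1).sum()
    )
    if n_missing_outcome:
        logger.info(
            "patient table %s: %d rows with at least one missing outcome (kept)",
            path,
            n_missing_outcome,
        )
    return df


def join_features_to_patients(
    features: pd.DataFrame,
    patients: pd.DataFrame,
    per_patient: str = "mean",
) -> pd.DataFrame:
    """Join spot-level features to the clinical table on ``patient_id``.

    Multiple spots per patient are combined by the per-patient mean by
    default (``per_patient='mean'``); ``per_patient='spot'`` keeps one row
    per spot instead.
    """
    feat_cols = [
        "n_nests",
        "total_area",
        "mean_area",
        "total_perimeter",
        "mean_perimeter",
        "mean_circularity",
        "mean_roundness",
    ]
    usable = features.loc[~features.get("excluded", 0).fillna(0).astype(bool)]
    if per_patient == "mean":
        agg = usable.groupby("patient_id", as_index=False)[feat_cols].mean()
    elif per_patient == "spot":
        agg = usable[["spot_id", "patient_id"] + feat_cols]
    else:
        raise ValueError(f"unknown per_patient mode: {per_patient!r}")
    merged = agg.merge(patients, on="patient_id", how="inner")
    if merged.empty:
        raise ValidationError("join of features and patients produced 0 rows")
    return merged
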