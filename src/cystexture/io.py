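"""Reading images and ROI masks, and round-tripping the cohort feature table.

Supported image formats: single-frame DICOM (spacing from the PixelSpacing
tag), NIfTI (spacing from pixdim; the first slice of a single-slice volume),
and plain rasters (PNG/TIFF), which carry no physical spacing and therefore
require an explicit ``spacing_override``. Masks are raster images binarized
at > 0; the freehand ROI of the clinical workflow is represented by its
rasterized equivalent.

Coordinate convention: row-major ``(row, col)``, 0-based. Pixel spacing is
isotropic in-plane (mm); anisotropic spacing is rejected rather than averaged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: statistics, in feature-table column order
STAT_NAMES = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")
#: default spatial scale factors (mm); 0 denotes the unfiltered image
DEFAULT_SCALES = (0.0, 2.0, 4.0, 6.0)

GROUPS = ("benign", "malignant")
SUBTYPES = {
    "functional_cyst": "benign",
    "serous_cystadenoma": "benign",
    "clear_cell_carcinoma": "malignant",
    "serous_carcinoma": "malignant",
}

#: smallest ROI for which 4th-moment estimates are accepted
MIN_ROI_PIXELS = 9

# spacings within this relative tolerance count as isotropic
_ISO_RTOL = 1e-6


def _ssf_tag(ssf_mm: float) -> str:
    """``0.0 -> '0'``, ``2.0 -> '2'``, ``2.5 -> '2.5'``."""
    return f"{ssf_mm:g}"


def feature_names(scales=DEFAULT_SCALES, stats=STAT_NAMES) -> list[str]:
    """Column names ``<stat>_ssf<k>``, statistics varying fastest per scale."""
    return [f"{s}_ssf{_ssf_tag(k)}" for k in scales for s in stats]


@dataclass(frozen=True)
class ImageSlice:
    """A single 2D T2-weighted slice with isotropic in-plane spacing (mm)."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    subject_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"image must be a non-empty 2D grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if not (self.pixel_spacing_mm > 0):
            raise ValueError(f"pixel_spacing_mm must be > 0, got {self.pixel_spacing_mm}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RoiMask:
    """Boolean grid marking fluid pixels; paired 1:1 with an :class:`ImageSlice`."""

    mask: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.size == 0:
            raise ValueError(f"mask must be a non-empty 2D grid, got shape {m.shape}")
        m = m > 0  # binarization; idempotent on boolean input
        if int(m.sum()) < MIN_ROI_PIXELS:
            raise ValueError(
                f"ROI has {int(m.sum())} pixels; at least {MIN_ROI_PIXELS} are "
                "required for stable 3rd/4th-moment estimates"
            )
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class CohortRecord:
    """One subject: group/subtype labels plus the extracted feature set."""

    subject_id: str
    group: str
    subtype: str
    features: "object" = None  # TextureFeatureSet; kept loose to avoid a cycle

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if SUBTYPES[self.subtype] != self.group:
            raise ValueError(
                f"subtype {self.subtype!r} is inconsistent with group {self.group!r}"
            )


def _validate_isotropic(sp_row: float, sp_col: float, source: str) -> float:
    if not np.isclose(sp_row, sp_col, rtol=_ISO_RTOL, atol=0.0):
        raise ValueError(
            f"anisotropic pixel spacing ({sp_row} x {sp_col} mm) in {source}; "
            "only isotropic in-plane spacing is supported"
        )
    return float(sp_row)


def _read_pixels_and_spacing(path: str):
    """Return (2D float array, spacing_mm or None)."""
    ext = os.path.splitext(path)[1].lower()
    if path.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asanyarray(img.dataobj).squeeze()
        if data.ndim == 3:
            if data.shape[2] != 1:
                raise ValueError(
                    f"{path}: expected a single-slice volume, got shape {data.shape}"
                )
            data = data[:, :, 0]
        if data.ndim != 2:
            raise ValueError(f"{path}: cannot interpret shape {data.shape} as one slice")
        zooms = img.header.get_zooms()[:2]
        return np.asarray(data, dtype=float), _validate_isotropic(zooms[0], zooms[1], path)
    if ext in (".dcm", ".dicom", ""):
        import pydicom

        ds = pydicom.dcmread(path)
        data = ds.pixel_array.astype(float)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected single-frame DICOM, got shape {data.shape}")
        spacing = None
        if getattr(ds, "PixelSpacing", None) is not None:
            spacing = _validate_isotropic(
                float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]), path
            )
        return data, spacing
    if ext in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path), dtype=float)
        if data.ndim == 3:  # collapse trivial channel axes
            data = data.mean(axis=2)
        return data, None
    raise ValueError(f"unsupported image format: {path}")


def read_image_with_mask(
    image_path: str,
    mask_path: str,
    spacing_override: float | None = None,
    subject_id: str | None = None,
) -> tuple[ImageSlice, RoiMask]:
    """Read a validated (image, mask) pair from disk.

    Spacing is taken from file metadata when present, else from
    ``spacing_override``. Raster inputs (PNG/TIFF) carry no spacing and make
    the override mandatory. The mask is binarized at > 0 and must match the
    image dimensions exactly.
    """
    for p in (image_path, mask_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    pixels, spacing = _read_pixels_and_spacing(image_path)
    if spacing is None:
        spacing = spacing_override
    if spacing is None:
        raise ValueError(
            f"{image_path}: no pixel spacing in file metadata and no "
            "spacing_override given; raster formats require an explicit spacing"
        )
    mask_px, _ = _read_pixels_and_spacing(mask_path)
    if mask_px.shape != pixels.shape:
        raise ValueError(
            f"image/mask dimension mismatch: image {pixels.shape} vs mask {mask_px.shape}"
        )
    sid = subject_id if subject_id is not None else os.path.splitext(os.path.basename(image_path))[0]
    return (
        ImageSlice(pixels=pixels, pixel_spacing_mm=float(spacing), subject_id=sid),
        RoiMask(mask=mask_px, subject_id=sid),
    )


def write_feature_table(records: list[CohortRecord], path: str) -> int:
    """Write one CSV row per subject; returns the row count.

    Columns: ``subject_id, group, subtype`` then the feature columns
    ``<stat>_ssf<k>`` in scale-major order. All records must be complete;
    an incomplete record raises, naming the missing columns.
    """
    if not records:
        cols = ["subject_id", "group", "subtype"] + feature_names()
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return 0
    scales = records[0].features.scales
    cols = feature_names(scales)
    rows = []
    for rec in records:
        missing = rec.features.missing_entries() if rec.features is not None else cols
        if rec.features is None or missing:
            raise ValueError(
                f"record {rec.subject_id!r} is incomplete; missing columns: "
                + ", ".join(missing)
            )
        row = {"subject_id": rec.subject_id, "group": rec.group, "subtype": rec.subtype}
        row.update(rec.features.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", "group", "subtype"] + cols)
    # repr-precision floats so a round-trip recovers values exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return len(df)


def read_feature_table(path: str) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path)
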