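"""First-order histogram statistics over ROI pixels of filtered images.

Six statistics per scale — mean, SD, entropy, MPP, skewness, kurtosis — over
the default four scales (SSF 0, 2, 4, 6 mm) give the 24-value feature set of
one lesion.

Conventions (each configurable, since the commercial tool's are unpublished):

* SD is the sample standard deviation (n-1 denominator); ROIs are small and
  the unbiased estimate is preferred.
* Skewness is Fisher-Pearson g1 = m3 / m2^1.5 and kurtosis defaults to
  *excess* g2 = m4 / m2^2 - 3 (Gaussian -> 0), with central moments taken
  with the n denominator. ``kurtosis_convention="pearson"`` drops the -3.
* MPP is the mean over strictly positive values; on an unfiltered magnitude
  image it coincides with the mean, and on band-pass output it reads as the
  mean bright-feature response. If no value is positive it is 0 and flagged.
* Entropy is Shannon entropy in bits over an ``nbins`` equal-width histogram
  spanning the ROI's own [min, max]; a constant ROI gives 0 with a flag.

Degenerate inputs never produce NaN: zero-variance ROIs report skewness =
kurtosis = 0 with a ``zero-variance`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    DEFAULT_SCALES,
    MIN_ROI_PIXELS,
    STAT_NAMES,
    ImageSlice,
    RoiMask,
    _ssf_tag,
    feature_names,
)
from .filtration import SIGMA_PER_SSF, FilterScale, apply_filter

DEFAULT_NBINS = 256

FLAG_ZERO_VARIANCE = "zero-variance"
FLAG_NO_POSITIVE = "no-positive-pixels"


@dataclass
class TextureFeatureSet:
    """All statistic x scale values for one lesion, plus degeneracy flags."""

    values: dict[tuple[str, float], float]
    flags: dict[tuple[str, float], str] = field(default_factory=dict)
    scales: tuple[float, ...] = DEFAULT_SCALES
    subject_id: str = ""

    def __getitem__(self, key: tuple[str, float]) -> float:
        return self.values[key]

    def as_dict(self) -> dict[str, float]:
        """Flat ``{'<stat>_ssf<k>': value}`` mapping in column order."""
        return {
            f"{s}_ssf{_ssf_tag(k)}": self.values[(s, k)]
            for k in self.scales
            for s in STAT_NAMES
            if (s, k) in self.values
        }

    def missing_entries(self) -> list[str]:
        return [
            f"{s}_ssf{_ssf_tag(k)}"
            for k in self.scales
            for s in STAT_NAMES
            if (s, k) not in self.values
        ]

    def __len__(self) -> int:
        return len(self.values)


def first_order_stats(
    pixels_in_roi,
    nbins: int = DEFAULT_NBINS,
    kurtosis_convention: str = "excess",
) -> tuple[dict[str, float], dict[str, str]]:
    """Compute the six statistics over a flat vector of ROI values.

    Returns ``(stats, flags)``. Requires at least 9 finite values; below that
    the 4th-moment estimate is meaningless and the call raises.
    """
    x = np.asarray(pixels_in_roi, dtype=float).ravel()
    if x.size < MIN_ROI_PIXELS:
        raise ValueError(
            f"need at least {MIN_ROI_PIXELS} ROI values, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("ROI contains non-finite values")
    if kurtosis_convention not in ("excess", "pearson"):
        raise ValueError(f"unknown kurtosis convention {kurtosis_convention!r}")

    n = x.size
    flags: dict[str, str] = {}
    mean = float(x.mean())
    centered = x - mean
    m2 = float((centered**2).mean())
    sd = float(np.sqrt((centered**2).sum() / (n - 1)))

    pos = x[x > 0]
    if pos.size:
        mpp = float(pos.mean())
    else:
        mpp = 0.0
        flags["mpp"] = FLAG_NO_POSITIVE

    if m2 == 0.0:
        skewness = 0.0
        kurtosis = 0.0
        flags["skewness"] = FLAG_ZERO_VARIANCE
        flags["kurtosis"] = FLAG_ZERO_VARIANCE
    else:
        m3 = float((centered**3).mean())
        m4 = float((centered**4).mean())
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2
        if kurtosis_convention == "excess":
            kurtosis -= 3.0

    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        entropy = 0.0
        flags["entropy"] = FLAG_ZERO_VARIANCE
    else:
        counts, _ = np.histogram(x, bins=nbins, range=(lo, hi))
        p = counts[counts > 0] / n
        entropy = float(-(p * np.log2(p)).sum())

    stats = {
        "mean": mean,
        "sd": sd,
        "entropy": entropy,
        "mpp": mpp,
        "skewness": skewness,
        "kurtosis": kurtosis,
    }
    return stats, flags


def extract_feature_set(
    image: ImageSlice,
    mask: RoiMask,
    scales=DEFAULT_SCALES,
    nbins: int = DEFAULT_NBINS,
    sigma_per_ssf: float = SIGMA_PER_SSF,
    kurtosis_convention: str = "excess",
) -> TextureFeatureSet:
    """Filter at each scale and compute ROI statistics of each derived image."""
    if image.shape != mask.mask.shape:
        raise ValueError(
            f"image/mask dimension mismatch: {image.shape} vs {mask.mask.shape}"
        )
    if len(scales) < 1:
        raise ValueError("need at least one scale")
    values: dict[tuple[str, float], float] = {}
    flags: dict[tuple[str, float], str] = {}
    scale_key = tuple(float(s) for s in scales)
    for ssf in scale_key:
        filtered = apply_filter(image, FilterScale(ssf, sigma_per_ssf))
        stats, st_flags = first_order_stats(
            filtered.pixels[mask.mask], nbins=nbins,
            kurtosis_convention=kurtosis_convention,
        )
        for stat, val in stats.items():
            values[(stat, ssf)] = val
        for stat, flag in st_flags.items():
            flags[(stat, ssf)] = flag
    return TextureFeatureSet(
        values=values, flags=flags, scales=scale_key, subject_id=image.subject_id
    )


class TextureFeatureExtractor:
    """Transformer mapping (image, mask) pairs to the per-lesion feature matrix.

    Stateless in the statistical sense — ``fit`` only validates parameters —
    but follows the fit/transform protocol so it can sit in a pipeline in
    front of a classifier.

    Parameters
    ----------
    scales : sequence of float, default (0, 2, 4, 6)
        Spatial scale factors in mm; 0 is the unfiltered image.
    nbins : int, default 256
        Equal-width histogram bins for the entropy estimate.
    sigma_per_ssf : float, default 1/sqrt(2)
        Gaussian width per mm of SSF (see :mod:`cystexture.filtration`).
    kurtosis_convention : {"excess", "pearson"}
        Excess kurtosis (Gaussian -> 0) or raw 4th standardized moment.

    Attributes
    ----------
    feature_names_ : list of str
        Column names of the transformed output, ``<stat>_ssf<k>``.
    n_features_out_ : int
        ``6 * len(scales)`` (24 at defaults).
    """

    def __init__(
        self,
        scales=DEFAULT_SCALES,
        nbins: int = DEFAULT_NBINS,
        sigma_per_ssf: float = SIGMA_PER_SSF,
        kurtosis_convention: str = "excess",
    ):
        self.scales = scales
        self.nbins = nbins
        self.sigma_per_ssf = sigma_per_ssf
        self.kurtosis_convention = kurtosis_convention

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "scales": self.scales,
            "nbins": self.nbins,
            "sigma_per_ssf": self.sigma_per_ssf,
            "kurtosis_convention": self.kurtosis_convention,
        }

    def set_params(self, **params):
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    # ---------------------------------------------------------------------
    def fit(self, X=None, y=None):
        if len(self.scales) < 1:
            raise ValueError("need at least one scale")
        if self.nbins < 2:
            raise ValueError("nbins must be >= 2")
        self.feature_names_ = feature_names(tuple(float(s) for s in self.scales))
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        """``X`` is a sequence of ``(ImageSlice, RoiMask)``; returns (n, 6*k)."""
        if not hasattr(self, "feature_names_"):
            self.fit()
        rows = [self.extract(img, msk).as_dict() for img, msk in X]
        return np.array([[r[name] for name in self.feature_names_] for r in rows])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def extract(self, image: ImageSlice, mask: RoiMask) -> TextureFeatureSet:
        """Full per-lesion feature set, with degeneracy flags preserved."""
        return extract_feature_set(
            image,
            mask,
            scales=self.scales,
            nbins=self.nbins,
            sigma_per_ssf=self.sigma_per_ssf,
            kurtosis_convention=self.kurtosis_convention,
        )
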