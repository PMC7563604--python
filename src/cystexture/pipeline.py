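"""End-to-end orchestration: simulate -> extract -> analyze, reproducibly.

A :class:`RunConfig` fully determines a run; it is embedded verbatim in the
report so any report can be regenerated from itself. Outputs under one run
directory: ``features.csv``, ``report.json``, ``registry.csv`` (synthetic
runs) and a stage-level log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from .features import DEFAULT_NBINS, TextureFeatureExtractor
from .filtration import SIGMA_PER_SSF
from .io import (
    DEFAULT_SCALES,
    CohortRecord,
    read_image_with_mask,
    write_feature_table,
)
from .stats import run_full_analysis
from .synthetic import PhantomParams, apply_exclusions, generate_cohort, generate_registry

logger = logging.getLogger("cystexture")


@dataclass(frozen=True)
class RunConfig:
    """Serializable recipe for one full analysis run."""

    scales: tuple[float, ...] = DEFAULT_SCALES
    nbins: int = DEFAULT_NBINS
    alpha: float = 0.05
    sigma_per_ssf: float = SIGMA_PER_SSF
    kurtosis_convention: str = "excess"
    seed: int = 42
    n_benign: int = 15
    n_malignant: int = 13
    cohort_csv: str | None = None  # user data; None -> synthetic cohort
    out_dir: str = "run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_extractor(config: RunConfig) -> TextureFeatureExtractor:
    return TextureFeatureExtractor(
        scales=tuple(config.scales),
        nbins=config.nbins,
        sigma_per_ssf=config.sigma_per_ssf,
        kurtosis_convention=config.kurtosis_convention,
    ).fit()


def extract_cohort_features(cohort, extractor: TextureFeatureExtractor) -> list[CohortRecord]:
    """``cohort``: iterable of (ImageSlice, RoiMask, group, subtype)."""
    records = []
    for img, msk, group, subtype in cohort:
        t0 = time.perf_counter()
        fs = extractor.extract(img, msk)
        logger.debug(
            "extracted %s (%d ROI px) in %.3f s", img.subject_id, msk.n_pixels,
            time.perf_counter() - t0,
        )
        records.append(
            CohortRecord(subject_id=img.subject_id, group=group, subtype=subtype, features=fs)
        )
    return records


def load_user_cohort(cohort_csv: str, spacing_override: float | None = None):
    """Read a user cohort table: subject_id, group, subtype, image, mask paths."""
    df = pd.read_csv(cohort_csv)
    required = {"subject_id", "group", "subtype", "image", "mask"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(cohort_csv))
    cohort = []
    for row in df.itertuples():
        img_path = row.image if os.path.isabs(row.image) else os.path.join(base, row.image)
        msk_path = row.mask if os.path.isabs(row.mask) else os.path.join(base, row.mask)
        img, msk = read_image_with_mask(
            img_path, msk_path, spacing_override=spacing_override,
            subject_id=str(row.subject_id),
        )
        cohort.append((img, msk, row.group, row.subtype))
    return cohort


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict and writes the bundle."""
    os.makedirs(config.out_dir, exist_ok=True)

    stage = "simulate"
    try:
        if config.cohort_csv is None:
            logger.info("stage %s: generating synthetic cohort (seed %d)", stage, config.seed)
            registry = generate_registry(config.seed)
            included = apply_exclusions(registry)
            logger.info(
                "registry: %d referrals, %d eligible after exclusions",
                len(registry), len(included),
            )
            pd.DataFrame(
                {"record_id": [r.record_id for r in registry],
                 "exclusion_flag": [r.exclusion_flag for r in registry]}
            ).to_csv(os.path.join(config.out_dir, "registry.csv"), index=False)
            cohort = generate_cohort(
                PhantomParams(
                    n_benign=config.n_benign, n_malignant=config.n_malignant,
                    seed=config.seed,
                )
            )
        else:
            logger.info("stage %s: loading user cohort from %s", stage, config.cohort_csv)
            cohort = load_user_cohort(config.cohort_csv)

        stage = "extract"
        logger.info("stage %s: %d subjects, scales %s", stage, len(cohort), config.scales)
        t0 = time.perf_counter()
        records = extract_cohort_features(cohort, build_extractor(config))
        logger.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)
        features_csv = os.path.join(config.out_dir, "features.csv")
        write_feature_table(records, features_csv)

        stage = "analyze"
        logger.info("stage %s: alpha = %g", stage, config.alpha)
        table = pd.read_csv(features_csv)
        report = run_full_analysis(table, alpha=config.alpha)
        report["config"] = config.to_dict()
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info(
            "significant features: %s", ", ".join(report["significant_features"]) or "(none)"
        )
        return report
    except Exception:
        logger.error("pipeline failed during stage %r", stage)
        raise
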