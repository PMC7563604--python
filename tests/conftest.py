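import numpy as np
import pandas as pd
import pytest

import cystexture as ct


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def cohort_feature_table(params: ct.PhantomParams, extractor=None) -> pd.DataFrame:
    """Generate a cohort and extract its full feature table."""
    extractor = extractor or ct.TextureFeatureExtractor().fit()
    rows = []
    for img, msk, group, subtype in ct.generate_cohort(params):
        d = extractor.extract(img, msk).as_dict()
        d.update(subject_id=img.subject_id, group=group, subtype=subtype)
        rows.append(d)
    cols = ["subject_id", "group", "subtype"] + extractor.feature_names_
    return pd.DataFrame(rows)[cols]


@pytest.fixture(scope="session")
def default_cohort_table() -> pd.DataFrame:
    """Default-size synthetic cohort (15 benign / 13 malignant), one fixed seed."""
    return cohort_feature_table(ct.PhantomParams(seed=42))


@pytest.fixture
def small_image_mask():
    """A 64x64 noisy slice with a centered 11x11 square ROI."""
    g = np.random.default_rng(7)
    img = ct.ImageSlice(100.0 + 10.0 * g.standard_normal((64, 64)), 0.75, "s1")
    mask = np.zeros((64, 64), dtype=bool)
    mask[27:38, 27:38] = True
    return img, ct.RoiMask(mask, "s1")
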