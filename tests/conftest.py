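import numpy as np
import pytest

from restoview.experiments import build_study_features

STUDY_SEED = 20240611


@pytest.fixture(scope="session")
def study_features():
    """One study-shaped synthetic photo set: 60 scenes, 12 groups, features.

    Built once per session; used by the end-to-end modeling checks.
    """
    features, manifest = build_study_features(seed=STUDY_SEED)
    return features, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_uniform_hsv_image(hue_deg, sat_pct, val_pct, shape=(20, 20)):
    """Uniform RGB image from HSV in degrees/percent (test helper)."""
    from skimage.color import hsv2rgb

    hsv = np.empty(shape + (3,), dtype=float)
    hsv[..., 0] = hue_deg / 360.0
    hsv[..., 1] = sat_pct / 100.0
    hsv[..., 2] = val_pct / 100.0
    rgb = np.clip(np.round(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    from restoview.images import RasterImage

    return RasterImage(rgb)
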