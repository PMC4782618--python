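import numpy as np
import pytest

from microbiopsy import enhance, segment, synthgen


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def normal_scene():
    return synthgen.generate_class_scene("normal", 11)


@pytest.fixture(scope="session")
def cancer_scene():
    return synthgen.generate_class_scene("cancerous", 11)


@pytest.fixture(scope="session")
def enhanced_roi(cancer_scene):
    """One full preprocessing chain: CLAHE + k-means + ROI selection."""
    enhanced = enhance.enhance_rgb(cancer_scene.image)
    mask = segment.kmeans_segment(enhanced, k=3, seed=7)
    roi = segment.select_roi(mask, enhanced, rule="most_blue")
    return enhanced, roi
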