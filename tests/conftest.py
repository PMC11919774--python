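import numpy as np
import pytest

from gazesal.saliency import compute_saliency
from gazesal.synthetic_data import generate_stimulus_set


@pytest.fixture(scope="session")
def stimulus_set():
    """Default 20-image synthetic stimulus set (4 per category)."""
    return generate_stimulus_set(0)


@pytest.fixture(scope="session")
def maps_by_channel(stimulus_set):
    """Four-channel saliency maps for every image, keyed [channel][image_id]."""
    out = {ch: {} for ch in ("full", "color", "luminance", "orientation")}
    for img, iid in zip(stimulus_set.images, stimulus_set.image_ids):
        for ch, m in compute_saliency(img, iid).items():
            out[ch][iid] = m
    return out


@pytest.fixture(scope="session")
def analysis_full_maps(stimulus_set, maps_by_channel):
    """Full-model maps of the 16 non-noise analysis images."""
    from gazesal.scoring import filter_images

    return [maps_by_channel["full"][iid] for iid in filter_images(stimulus_set)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
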