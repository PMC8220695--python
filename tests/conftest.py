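import numpy as np
import pytest

from floramet import RenderSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """8 well-separated synthetic classes x 6 originals at 64 px."""
    out = tmp_path_factory.mktemp("smallset")
    spec = RenderSpec(image_size=64, background_mode="uniform", global_seed=11)
    manifest = generate_dataset(
        8, 6, spec, out, min_hue_sep=40.0, texture_scale=0.01
    )
    return manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
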