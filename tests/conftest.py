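import numpy as np
import pytest

from histomil.synthetic import SyntheticSlideSpec, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """One deterministic 512-px synthetic slide with all five morphologies."""
    spec = SyntheticSlideSpec(width=512, height=512, mutation_patch_size=64,
                              seed=11)
    return generate_slide(spec, slide_id="fixture")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
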