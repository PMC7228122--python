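import numpy as np
import pytest

from otolookup import LabeledImage, SynthSpec, TinyCNN, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    return SynthSpec(
        n_per_class=4,
        image_height=64,
        image_width=64,
        separability=1.0,
        margin_fraction=0.1,
        timestamp=True,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def tiny_backbone() -> TinyCNN:
    return TinyCNN(seed=1)


def random_image(rng: np.random.Generator, label="normal", id_="img", size=(16, 16)):
    px = rng.integers(0, 256, size=(*size, 3), dtype=np.uint8)
    return LabeledImage(px, label, id_)
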