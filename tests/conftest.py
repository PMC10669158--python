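import numpy as np
import pytest

from leafdiffuse import (
    DiseaseStyle,
    LeafSpec,
    apply_disease,
    build_noise_schedule,
    generate_leaf,
    train_epsilon_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_schedule():
    """A 50-step linear schedule sized for desk-scale chains."""
    return build_noise_schedule(50, "linear", 1e-4, 0.25)


def make_two_class_leaves(n=64, size=16, seed_base=1000):
    """Seeded 16x16 leaf set, alternating healthy / dark-spot diseased."""
    style = DiseaseStyle("dark-spot", intensity=0.8)
    spec = LeafSpec(size=size)
    images = []
    for i in range(n):
        r = np.random.default_rng(seed_base + i)
        img, mask = generate_leaf(spec, r)
        if i % 2 == 1:
            img = apply_disease(img, mask, style, r)
        images.append(img)
    return np.stack(images)


@pytest.fixture(scope="session")
def leaf_images16():
    return make_two_class_leaves()


@pytest.fixture(scope="session")
def trained_tiny_model(leaf_images16, tiny_schedule):
    """A <=50k-parameter noise model trained 2000 steps on 64 tiny leaves."""
    model = train_epsilon_model(
        leaf_images16,
        tiny_schedule,
        hidden=28,
        steps=2000,
        batch_size=32,
        lr=1e-3,
        rng=np.random.default_rng(7),
    )
    assert model.n_params <= 50_000
    return model
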