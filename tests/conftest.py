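import numpy as np
import pytest

from equinodes.detector import TrainingConfig, train_detector
from equinodes.synthetic import SyntheticParams, generate_dataset
from equinodes.types import TaxonLabel


@pytest.fixture(scope="session")
def small_dataset():
    """18 synthetic specimens (6 per taxon) at default generator settings."""
    images, manifest = generate_dataset(6, SyntheticParams(), seed=7)
    return images, manifest


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    """A two-type detector trained once and shared across detector tests."""
    images, _ = small_dataset
    pure = [i for i in images if i.taxon != TaxonLabel.FERRISSII]
    train = pure[:4] + pure[6:10]
    val = pure[4:6] + pure[10:12]
    model, history = train_detector(
        train, val, TrainingConfig(max_iterations=1500), seed=5
    )
    return model, history


def random_boxes(rng: np.random.Generator, n: int, extent: float = 100.0) -> np.ndarray:
    """n random valid boxes inside [0, extent)^2."""
    x0 = rng.uniform(0, extent * 0.8, n)
    y0 = rng.uniform(0, extent * 0.8, n)
    w = rng.uniform(1.0, extent * 0.3, n)
    h = rng.uniform(1.0, extent * 0.3, n)
    return np.stack([x0, y0, np.minimum(x0 + w, extent), np.minimum(y0 + h, extent)], axis=1)
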