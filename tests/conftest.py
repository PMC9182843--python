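import numpy as np
import pytest

from msgait.backbone import BackboneConfig, LayerSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A three-layer plan small enough for brute-force checks."""
    return BackboneConfig(
        layers=(
            LayerSpec("conv", 3, 8, 1, "valid"),
            LayerSpec("maxpool", 2, 0, 2),
            LayerSpec("conv", 3, 8, 2, "same"),
        ),
        dropout_rate=0.0,
        l2_reg=1e-4,
    )


def loo_nearest_centroid(X, y):
    """Leave-one-out nearest-centroid accuracy on flattened windows.

    Independent oracle used to check the generator's class separability.
    """
    X = X.reshape(len(X), -1)
    y = np.asarray(y)
    classes = np.unique(y)
    hits = 0
    for i in range(len(X)):
        mask = np.ones(len(X), bool)
        mask[i] = False
        cents = np.stack([X[mask & (y == c)].mean(axis=0) for c in classes])
        pred = classes[np.linalg.norm(cents - X[i], axis=1).argmin()]
        hits += pred == y[i]
    return hits / len(X)
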