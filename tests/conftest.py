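import numpy as np
import pytest

from mammosrc import ClusterSpec, PhantomSpec, gen_feature_clusters, gen_roi
from mammosrc.dataset import FeatureSet
from mammosrc.roi import ROIPatch


@pytest.fixture(scope="session")
def spiculated_patch():
    return gen_roi(PhantomSpec(margin_type="spiculated", seed=7))


@pytest.fixture(scope="session")
def circumscribed_patch():
    return gen_roi(PhantomSpec(margin_type="circumscribed", seed=7))


@pytest.fixture(scope="session")
def normal_patch():
    return gen_roi(PhantomSpec(margin_type="normal", seed=7))


@pytest.fixture
def toy_patch():
    """5x4 two-level patch with a partial mask, for hand-countable oracles."""
    pixels = np.array([
        [0.0, 0.0, 1.0, 1.0],
        [0.0, 1.0, 1.0, 0.0],
        [1.0, 1.0, 0.0, 0.0],
        [1.0, 0.0, 0.0, 1.0],
        [0.0, 1.0, 0.0, 1.0],
    ])
    mask = np.array([
        [1, 1, 1, 1],
        [1, 1, 1, 1],
        [1, 1, 1, 1],
        [1, 1, 1, 0],
        [1, 1, 1, 1],
    ], dtype=bool)
    return ROIPatch(pixels, mask)


@pytest.fixture(scope="session")
def small_cluster_set():
    """A small draw of the standard benchmark geometry."""
    return gen_feature_clusters(
        ClusterSpec.balanced(n_per_margin=15, n_normal=75, seed=42))


def two_class_set(n_per_class=25, d=8, gap=6.0, seed=0) -> FeatureSet:
    """Two well-separated Gaussian classes (masses all one margin)."""
    rng = np.random.default_rng(seed)
    Xm = rng.standard_normal((n_per_class, d)) + gap / np.sqrt(d)
    Xn = rng.standard_normal((n_per_class, d))
    X = np.vstack([Xm, Xn])
    labels = np.array(["mass"] * n_per_class + ["normal"] * n_per_class,
                      dtype=object)
    margins = np.array(["circumscribed"] * n_per_class + [None] * n_per_class,
                       dtype=object)
    return FeatureSet(X, labels, margins)
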