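import numpy as np
import pytest

import fuzzyhisto as fh


@pytest.fixture(scope="session")
def separable_table():
    """Strongly separable tabular fixture: 200 samples, 20 features, 5 planted."""
    return fh.make_feature_table(fh.FixtureSpec(
        n_per_class=100, n_features=20, n_informative=5,
        class_separation=6.0, seed=11))


@pytest.fixture(scope="session")
def small_images():
    """Six 32-px tiles, three per class."""
    return fh.make_images(fh.FixtureSpec(n_per_class=3, image_size=32, seed=7))


@pytest.fixture
def triangular_partition():
    """Uniform 3-level triangular partition of [0, 2] (centers 0, 1, 2)."""
    return fh.build_partition(np.array([0.0, 2.0]), "x", n_levels=3)
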