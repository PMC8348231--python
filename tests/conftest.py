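from pathlib import Path

import numpy as np
import pytest

from solvar import (
    FeatureSpace,
    FixtureSpec,
    generate_fixture,
    load_aaindex,
    write_synthetic_aaindex,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mini_aaindex():
    """Two real property scales (isoelectric point, hydropathy) + one NA entry."""
    return load_aaindex(DATA_DIR / "aaindex_mini.txt")


@pytest.fixture(scope="session")
def synth_aaindex_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("aaindex") / "synthetic_aaindex.txt"
    write_synthetic_aaindex(path, seed=5)
    return path


@pytest.fixture(scope="session")
def synth_space(synth_aaindex_path):
    """Feature space over the synthetic stand-in AAindex table (22 scales)."""
    return FeatureSpace(load_aaindex(synth_aaindex_path))


@pytest.fixture(scope="session")
def small_dataset():
    """300 planted-rule variants over 5 random proteins."""
    return generate_fixture(FixtureSpec(n_proteins=5, n_variants=300, signal=1.0, seed=1))


@pytest.fixture(scope="session")
def small_matrix(synth_space, small_dataset):
    X = synth_space.matrix(small_dataset)
    y = np.array([v.label for v in small_dataset.variants])
    return X, y
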