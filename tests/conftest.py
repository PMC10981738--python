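import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plmhomology import FixtureSpec, make_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted-fold fixture: 5 folds x 20 proteins, seed 7."""
    return make_dataset(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 12-protein fixture for fast structural checks."""
    return make_dataset(
        FixtureSpec(
            n_folds=3,
            superfamilies_per_fold=2,
            families_per_superfamily=1,
            proteins_per_family=2,
            dim=8,
            seq_length=(10, 16),
            seed=3,
        )
    )
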