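import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from floaterqg.pedigree import Pedigree, additive_relationship
from floaterqg.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (pedigree + phenotypes)."""
    return simulate_dataset(SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def default_relatedness(default_dataset):
    ped, _ = default_dataset
    return additive_relationship(ped)


@pytest.fixture()
def trio_pedigree():
    """Founder pair plus one offspring: the minimal valid pedigree."""
    return Pedigree.from_records(
        [("S", None, None, 2000, "M"), ("D", None, None, 2000, "F"),
         ("X", "S", "D", 2001, "M")]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
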