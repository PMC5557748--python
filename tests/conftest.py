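import numpy as np
import pytest

from symh2.io import OtuCountTable, OtuSequenceSet
from symh2.simulate import StudyConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_table():
    return OtuCountTable(["OTU1", "OTU2"], ["s1", "s2"], np.array([[3, 0], [1, 5]]))


@pytest.fixture
def tiny_seqs():
    return OtuSequenceSet({"OTU1": "ACGT", "OTU2": "AC-T"})


@pytest.fixture(scope="session")
def diallel_bundle():
    """One half-diallel synthetic study reused by read-only tests."""
    config = StudyConfig(
        design="half_diallel",
        n_parents=8,
        n_families=20,
        offspring_per_family=10,
        sigma2_a=0.3,
        sigma2_e=0.7,
        seed=101,
    )
    return simulate_study(config)


@pytest.fixture(scope="session")
def maternal_bundle():
    config = StudyConfig(
        design="maternal_only",
        n_parents=9,
        n_families=9,
        offspring_per_family=11,
        sigma2_a=0.6,
        sigma2_e=0.4,
        seed=202,
    )
    return simulate_study(config)
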