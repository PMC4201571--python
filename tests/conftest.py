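import numpy as np
import pytest

from pepperm import Peptide, RunConfig, generate_synthetic_database


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


@pytest.fixture
def tiny_db(rng):
    return generate_synthetic_database(10, rng, length_dist=10, name="tiny")


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def pep_ag():
    return Peptide("AG", peptide_id="ag")
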