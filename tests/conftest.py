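import numpy as np
import pytest

from regseq.motif_model import MotifRecord, PositionMatrix
from regseq.multimer_builder import DimerAnnotation
from regseq.synthetic_data import SyntheticSpec, make_dimer_catalog, make_monomer_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, length=8, concentration=0.5):
    """Random PositionMatrix with Dirichlet columns (no uniform columns)."""
    probs = rng.dirichlet([concentration] * 4, size=length)
    return PositionMatrix(probs)


def one_hot_matrix(word):
    """Deterministic matrix whose consensus is ``word``."""
    idx = ["ACGT".index(c) for c in word]
    return PositionMatrix(np.eye(4)[idx])


def make_record(motif_id, matrix, members=None):
    members = tuple(members) if members else (motif_id,)
    return MotifRecord(id=motif_id, tf_members=members, matrix=matrix)


@pytest.fixture
def small_spec():
    return SyntheticSpec(n_tfs=40, palindrome_fraction=0.4, seed=7)


@pytest.fixture
def monomers(small_spec):
    return make_monomer_catalog(small_spec)


@pytest.fixture
def dimers(small_spec, monomers):
    return make_dimer_catalog(monomers, small_spec)
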