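import numpy as np
import pytest

from mirrorhh import RIBOZYME_33NT, SUBSTRATE_14NT
from mirrorhh.complex_model import (
    build_heterochiral,
    hammerhead_pairing,
    restrained_refine,
)
from mirrorhh.synthetic import A_FORM, B_FORM, build_duplex, build_hammerhead_scaffold


@pytest.fixture(scope="session")
def substrate_seq() -> str:
    return SUBSTRATE_14NT


@pytest.fixture(scope="session")
def ribozyme_seq() -> str:
    return RIBOZYME_33NT


@pytest.fixture(scope="session")
def pairing(ribozyme_seq, substrate_seq):
    return hammerhead_pairing(ribozyme_seq, substrate_seq)


@pytest.fixture(scope="session")
def a_duplex():
    """Mixed-sequence ideal A-form duplex."""
    return build_duplex("GACUGUCA", A_FORM)


@pytest.fixture(scope="session")
def b_duplex():
    return build_duplex("GACUGUCA", B_FORM)


@pytest.fixture(scope="session")
def scaffold(ribozyme_seq, substrate_seq, pairing):
    """The all-D hammerhead analysis scaffold (47 residues, 1000 atoms)."""
    return build_hammerhead_scaffold(ribozyme_seq, substrate_seq, pairing)


@pytest.fixture(scope="session")
def refined_dd(scaffold, pairing):
    refined, trace = restrained_refine(scaffold, pairing)
    return refined, trace


@pytest.fixture(scope="session")
def hetero_ld(refined_dd, pairing):
    """L-RNA/D-Rz: substrate strand enantiomerized and refined."""
    dd, _ = refined_dd
    return build_heterochiral(dd, "S", pairing)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
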