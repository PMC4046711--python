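import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mpalign import (
    BioSequence,
    build_default_joint_model,
    build_nucleotide_model,
)
from mpalign.pairhmm import PairHMMParams


@pytest.fixture(scope="session")
def protein_model():
    return build_default_joint_model("protein")


@pytest.fixture(scope="session")
def nt_model():
    return build_nucleotide_model(0.3)


@pytest.fixture(scope="session")
def toy_params(nt_model):
    """Small nucleotide pair-HMM used for enumeration-scale checks."""
    return PairHMMParams.from_gap_params(
        delta=0.1, epsilon=0.4, tau=0.1, topology="full", match_emission=nt_model
    )


@pytest.fixture(scope="session")
def protein_params(protein_model):
    return PairHMMParams.from_gap_params(match_emission=protein_model)


def random_seq(rng, model, n, name="s"):
    idx = rng.choice(len(model.alphabet), size=n, p=model.marginal)
    return BioSequence(
        name, "".join(model.alphabet[i] for i in idx), model.alphabet_kind
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240114)
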