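import numpy as np
import pytest

from transpred.seqio import AMINO_ACIDS, ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, length, seq_id="q", probs=None):
    idx = rng.choice(20, size=length, p=probs)
    return ProteinSequence(seq_id, "".join(AMINO_ACIDS[i] for i in idx))


@pytest.fixture
def random_protein_factory():
    return random_protein
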