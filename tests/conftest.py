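import numpy as np
import pytest
from hypothesis import settings

from holocomp.kaks import CODON_TABLE, STOP_CODONS

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

NONSTOP_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_codon_seq(rng, n_codons):
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
    return "".join(NONSTOP_CODONS[i] for i in idx)


def random_dna(rng, length):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=length)])
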