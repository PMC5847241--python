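import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mirsnp.seqio import MatureMiRNA  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20090912)


@pytest.fixture
def tiny_corpus():
    return [
        MatureMiRNA("mir-a", "ACGUACG"),
        MatureMiRNA("mir-b", "ACGUUCG"),
        MatureMiRNA("mir-c", "ACGAACG"),
    ]


def random_rna(rng, length):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, length))


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
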