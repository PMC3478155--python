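import random

import pytest

from mirkit.io import SequenceRecord


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20260920)


@pytest.fixture
def let7():
    # a well-known conserved mature miRNA sequence, used as a generic probe
    return SequenceRecord(id="let-7a", sequence="UGAGGUAGUAGGUUGUAUAGUU")
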