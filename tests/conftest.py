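import numpy as np
import pytest

from degdet.sequences import ProteinDataset, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_dataset():
    seqs = {
        "p1": "M" + "A" * 40 + "I" * 30,          # hydrophobic tail
        "p2": "M" + "L" * 35 + "R" * 30,          # hydrophilic tail, hydrophobic rest
        "p3": "MGG" + "K" * 60 + "V" * 10,
        "p4": "M" + "S" * 70 + "GG",
        "p5": "MKFERQ" + "T" * 60,
    }
    return ProteinDataset("toy", [ProteinRecord(k, v) for k, v in seqs.items()])
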