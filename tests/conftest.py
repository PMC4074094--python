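import numpy as np
import pytest

from prionnet.bias import BackgroundComposition
from prionnet.datasets import DisorderTrack, ProteinRecord, ProteinSet
from prionnet.network import InteractionNetwork


@pytest.fixture(scope="session")
def uniform_bg() -> BackgroundComposition:
    return BackgroundComposition.uniform()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def triangle_network() -> InteractionNetwork:
    return InteractionNetwork([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture()
def toy_tracks() -> dict[str, DisorderTrack]:
    return {
        "A": DisorderTrack("A", 10, 5.0),
        "B": DisorderTrack("B", 30, 15.0),
        "C": DisorderTrack("C", 20, 0.0),
    }


def random_record(rng: np.random.Generator, accession: str, length: int) -> ProteinRecord:
    from prionnet.bias import AMINO_ACIDS

    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinRecord(accession, "".join(letters))


@pytest.fixture()
def small_set() -> ProteinSet:
    return ProteinSet("S", {"A", "B"})
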