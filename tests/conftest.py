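import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from posim.seqio import STANDARD_RESIDUES, InteractionTable, SequenceRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_RESIDUES), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset() -> tuple[list[SequenceRecord], InteractionTable]:
    """Two separable groups: class members share a sequence, complement differs."""
    member_seq = "ACDEFGHIKLMNPQRSTVWY" * 2
    other_seq = "YWVTSRQPNMLKIHGFEDCA" * 2
    records = [
        SequenceRecord("A1", member_seq),
        SequenceRecord("A2", member_seq),
        SequenceRecord("A3", member_seq),
        SequenceRecord("B1", other_seq),
        SequenceRecord("B2", other_seq),
        SequenceRecord("B3", other_seq),
    ]
    table = InteractionTable(
        [r.id for r in records],
        ["L1"],
        np.array([[1], [1], [1], [0], [0], [0]]),
    )
    return records, table
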