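import numpy as np
import pytest
from hypothesis import settings

from phytamyloid import ProteinRecord, ScoringMatrix
from phytamyloid.sequence_io import CANONICAL_AA

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def q_matrix() -> ScoringMatrix:
    """Indicator matrix: score 1 for Q at every position, threshold 4."""
    return ScoringMatrix.indicator("Q", window_length=6, threshold=4.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def random_protein(rng: np.random.Generator, pid: str, length: int,
                   alphabet: str = CANONICAL_AA) -> ProteinRecord:
    seq = "".join(rng.choice(list(alphabet), size=length))
    return ProteinRecord(id=pid, sequence=seq)
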