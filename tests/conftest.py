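import numpy as np
import pytest

from hawkdove.game import GameRecord, PayoffMatrix


@pytest.fixture
def matrix() -> PayoffMatrix:
    return PayoffMatrix(transfer=500.0, crash_cost=1000.0, scale=1000.0)


def record_from_codes(codes_1: str, codes_2: str, matrix=None, pair_id="fix") -> GameRecord:
    """Build a record from action strings like 'ARRA' (per player)."""
    assert len(codes_1) == len(codes_2)
    actions = np.array(
        [[0 if c == "A" else 1 for c in codes_1], [0 if c == "A" else 1 for c in codes_2]],
        dtype=np.int8,
    ).T
    return GameRecord(pair_id, actions, matrix=matrix)


@pytest.fixture
def switching_record(matrix) -> GameRecord:
    """Strict 100-trial alternation: roles swap every trial."""
    return record_from_codes("RA" * 50, "AR" * 50, matrix)


@pytest.fixture
def mixed_record(matrix) -> GameRecord:
    """Hand-constructed 10-trial mixed sequence used by window-count oracles."""
    return record_from_codes("RARRAARRRA", "ARRAAARARA", matrix)
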