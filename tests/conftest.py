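import pytest

from dnalz.rank import RankOrder
from dnalz.synthetic import WORKED_RANK, WORKED_SEQUENCE, golden_examples


@pytest.fixture(scope="session")
def golden():
    """Pinned intermediates of the 30-base worked example."""
    return golden_examples()


@pytest.fixture(scope="session")
def worked_rank():
    return RankOrder.from_string(WORKED_RANK)


@pytest.fixture(scope="session")
def worked_sequence():
    return WORKED_SEQUENCE


def all_bitstrings(max_len):
    """Every bitstring of length 0..max_len, shortest first."""
    for length in range(max_len + 1):
        for value in range(1 << length):
            yield format(value, f"0{length}b") if length else ""
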