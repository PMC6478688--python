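import numpy as np
import pytest

from lineagemotifs.core import CellRecord, build_forest
from lineagemotifs.simulate import fixture_toy_forest


def make_binary_lineage(lineage_id: str, depth: int, durations=None,
                        complete=None) -> list[CellRecord]:
    """Complete binary tree of ``depth`` generations, heap-numbered cells.

    ``durations`` maps heap number -> hours (default: distinct values
    10 + num/100); ``complete`` maps heap number -> bool (default True).
    """
    durations = durations or {}
    complete = complete or {}
    records = []
    for g in range(1, depth + 1):
        for num in range(2 ** (g - 1), 2 ** g):
            records.append(CellRecord(
                cell_id=f"{lineage_id}.{num}",
                lineage_id=lineage_id,
                parent_id=None if num == 1 else f"{lineage_id}.{num // 2}",
                generation=g,
                duration=float(durations.get(num, 10 + num / 100)),
                complete=bool(complete.get(num, True)),
            ))
    return records


def set_lineage(lineage_id: str, gen3_durations) -> list[CellRecord]:
    """3-generation lineage whose single granddaughter set has the given durations."""
    d = {4 + i: v for i, v in enumerate(gen3_durations)}
    return make_binary_lineage(lineage_id, 3, durations=d)


@pytest.fixture
def toy_forest():
    return fixture_toy_forest()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
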