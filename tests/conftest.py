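import numpy as np
import pandas as pd
import pytest

from nondirtest import ScenarioParams, TrialTable, simulate_scenario
from nondirtest.data import ParticipantData


def make_part(y0, y1, pid="p1", accuracy=None, confidence=None):
    """ParticipantData from per-condition outcome lists (0 = negative level)."""
    y0 = np.asarray(y0, float)
    y1 = np.asarray(y1, float)
    return ParticipantData(
        pid=pid,
        y=np.concatenate([y0, y1]),
        cond=np.r_[np.zeros(y0.size, int), np.ones(y1.size, int)],
        accuracy=None if accuracy is None else np.asarray(accuracy, float),
        confidence=None if confidence is None else np.asarray(confidence, float),
    )


def make_table(cells: dict, levels=("a", "b")) -> TrialTable:
    """TrialTable from {pid: (y0, y1)} per-condition outcome lists."""
    rows = []
    for pid, (y0, y1) in cells.items():
        for lvl, ys in zip(levels, (y0, y1)):
            for y in ys:
                rows.append({"participant": pid, "condition": lvl, "outcome": y})
    return TrialTable(pd.DataFrame(rows), levels=levels)


@pytest.fixture
def mk_part():
    return make_part


@pytest.fixture
def mk_table():
    return make_table


@pytest.fixture(scope="session")
def nd_dataset():
    """One dataset from the non-directional differences scenario."""
    return simulate_scenario(ScenarioParams.non_directional(), seed=11)


@pytest.fixture(scope="session")
def gn_dataset():
    """One dataset from the global-null scenario."""
    return simulate_scenario(ScenarioParams.global_null(), seed=12)
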