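from datetime import date, datetime

import numpy as np
import pytest

from proxnet.contacts import build_dyad_index, build_epoch_grid
from proxnet.io import DetectionRecord, Roster


@pytest.fixture
def small_grid():
    """Two days of 30-minute epochs (I = 96)."""
    return build_epoch_grid(date(2018, 1, 1), date(2018, 1, 2), 30)


@pytest.fixture
def abc_dyads():
    return build_dyad_index(["a", "b", "c"])


@pytest.fixture
def abc_roster():
    return Roster([("a", "dev-a"), ("b", "dev-b"), ("c", "dev-c")])


@pytest.fixture
def sample_records():
    return [
        DetectionRecord(datetime(2018, 1, 1, 9, 5), "a", "b"),
        DetectionRecord(datetime(2018, 1, 1, 9, 10), "b", "a"),
        DetectionRecord(datetime(2018, 1, 1, 9, 40), "a", "c"),
        DetectionRecord(datetime(2018, 1, 2, 14, 0), "b", "c"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
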