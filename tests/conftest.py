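from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reefshark.simulate import SyntheticTruth, synthetic_s1_table
from reefshark.tagging import IncrementDataset, TagRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def s1_dataset() -> IncrementDataset:
    """The packaged synthetic stand-in for the study's recapture table."""
    return synthetic_s1_table()


@pytest.fixture(scope="session")
def default_truth() -> SyntheticTruth:
    return SyntheticTruth()


def make_record(
    iid="a",
    sex="female",
    tl1=100.0,
    tl2=110.0,
    days=365,
    start=date(2008, 1, 1),
) -> TagRecord:
    return TagRecord(
        individual_id=iid,
        sex=sex,
        release_date=start,
        release_tl=tl1,
        recapture_date=start + timedelta(days=days),
        recapture_tl=tl2,
    )


@pytest.fixture
def toy_dataset() -> IncrementDataset:
    recs = [
        make_record("a", tl1=100.0, tl2=103.5, days=365),
        make_record("b", tl1=120.0, tl2=122.0, days=730),
        make_record("c", tl1=140.0, tl2=141.0, days=1096),
    ]
    return IncrementDataset.from_records(recs)
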