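import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the independent oracles

from adipoquant import Maturation, Race, Sex, SubjectRecord


@pytest.fixture
def male_subject():
    """A fully-measured 15.5-year-old white male."""
    return SubjectRecord(
        subject_id="m1",
        sex=Sex.MALE,
        age=15.5,
        weight=60.0,
        height=170.0,
        race=Race.WHITE,
        maturation=Maturation.POSTPUBESCENT,
        skinfolds={"biceps": 5.0, "triceps": 5.0, "suprailiac": 5.0,
                   "subscapular": 5.0, "midaxillary": 8.0, "calf": 10.0},
        brachial_perimeter=28.0,
        resistance=500.0,
        bia2_percent_fat=15.0,
        group="eutrophic",
    )


@pytest.fixture
def female_subject():
    """A fully-measured 17.2-year-old white female."""
    return SubjectRecord(
        subject_id="f1",
        sex=Sex.FEMALE,
        age=17.2,
        weight=55.0,
        height=160.0,
        race=Race.WHITE,
        maturation=Maturation.POSTPUBESCENT,
        skinfolds={"biceps": 5.0, "triceps": 14.0, "suprailiac": 5.0,
                   "subscapular": 12.0, "midaxillary": 10.0, "calf": 12.0},
        brachial_perimeter=26.0,
        resistance=600.0,
        bia2_percent_fat=25.0,
        group="eutrophic",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230516)
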