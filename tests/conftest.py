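import math

import pytest

from islert.data_model import (
    ColonistRecord,
    IslandDataset,
    MainlandPool,
    RateSet,
)
from islert.synthetic_data import (
    generate_checklist,
    m26_rates,
    madagascar_counts,
    madagascar_pool,
    madagascar_truth_config,
)


@pytest.fixture(scope="session")
def preferred_rates():
    return m26_rates()


@pytest.fixture(scope="session")
def study_pool():
    return madagascar_pool()


@pytest.fixture(scope="session")
def study_counts():
    return madagascar_counts()


@pytest.fixture(scope="session")
def study_checklist():
    return generate_checklist(madagascar_truth_config(), seed=0)


@pytest.fixture()
def small_dataset():
    """A hand-built valid dataset with all record flavours."""
    pool = MainlandPool(M=100, p_guild2=0.3, island_age=20.0)
    recs = (
        ColonistRecord("nv_radiation", "nonvolant", "precise", 15.0,
                       (9.0, 4.0, 1.5), "endemic", 0),
        ColonistRecord("nv_singleton", "nonvolant", "precise", 3.0, (),
                       "endemic", 0),
        ColonistRecord("bat_ne", "bat", "max_age", 6.0, (), "non_endemic", 0),
        ColonistRecord("bat_mixed", "bat", "precise", 11.0, (5.0,),
                       "endemic_and_non_endemic", 0),
    )
    return IslandDataset(pool=pool, colonists=recs, label="toy")


@pytest.fixture(scope="session")
def generic_rates():
    return RateSet(gamma=0.05, lambda_c=0.3, lambda_a=0.5, mu=0.25, K=math.inf)
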