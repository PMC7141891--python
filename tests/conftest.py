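import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import microquant as mq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return mq.CohortConfig(n_participants=4, duration_days=30, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return mq.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    _, qpcr, abund = small_cohort
    res = mq.join_tables(qpcr, abund)
    return mq.build_error_records(mq.infer_table(res.pairs))


@pytest.fixture()
def qpcr_csv(tmp_path):
    path = tmp_path / "qpcr.csv"
    path.write_text(
        "participant_id,time_h,total_load,L_crispatus,G_vaginalis\n"
        "P01,24,1e7,5e6,93.8\n"
        "P01,48,2e7,1e7,1e3\n"
        "P02,24,5e5,93.8,2e5\n"
    )
    return path


@pytest.fixture()
def abundance_csv(tmp_path):
    path = tmp_path / "abundance.csv"
    path.write_text(
        "participant_id,time_h,L_crispatus,G_vaginalis,Prevotella_bivia\n"
        "P01,24,60,30,10\n"
        "P01,48,80,0,20\n"
        "P02,24,5,90,5\n"
    )
    return path
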