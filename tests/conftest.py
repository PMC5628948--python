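import numpy as np
import pytest

from fetalgrowth.cohort import CohortConfig, generate_cohort
from fetalgrowth.config import default_customization_model, default_iga_config
from fetalgrowth.lms import model_from_centile_table, tvol_reference


@pytest.fixture(scope="session")
def tvol_table():
    return tvol_reference()


@pytest.fixture(scope="session")
def tvol_model(tvol_table):
    """Age-indexed LMS model back-solved from the shipped weekly table."""
    return model_from_centile_table(tvol_table)


@pytest.fixture(scope="session")
def iga_cfg():
    return default_iga_config()


@pytest.fixture(scope="session")
def customization():
    return default_customization_model()


@pytest.fixture(scope="session")
def cohort_seed1():
    """One default synthetic cohort, reused read-only across tests."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_bundle():
    from fetalgrowth.config import PipelineConfig
    from fetalgrowth.pipeline import run_pipeline

    return run_pipeline(PipelineConfig(out_dir=None, seed=1, log_level="WARNING"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
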