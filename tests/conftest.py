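import numpy as np
import pytest

from periopcea.parameters import packaged_table
from periopcea.pipeline import ModelSettings, build_engine_config, run_base_case


@pytest.fixture(scope="session")
def table():
    return packaged_table()


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def base_result(table, settings):
    return run_base_case(table, settings)


@pytest.fixture(scope="session")
def engine_config(table, settings):
    return build_engine_config(table, settings)


@pytest.fixture(scope="session")
def psa_run(table, settings):
    """One seeded 1,000-repetition PSA shared by the analyses that need it."""
    from periopcea.uncertainty import run_psa

    return run_psa(table, n=1000, seed=1234, settings=settings)
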