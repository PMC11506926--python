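import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from piperpbpk import (DEFAULT_PHYSIOLOGY, ddi_table, load_tissue_table,
                       piperine, victim_fixtures)


@pytest.fixture(scope="session")
def piperine_params():
    return piperine()


@pytest.fixture(scope="session")
def physiology():
    return DEFAULT_PHYSIOLOGY


@pytest.fixture(scope="session")
def tissue_table():
    return load_tissue_table()


@pytest.fixture(scope="session")
def victims():
    return {v.name: v for v in victim_fixtures()}


@pytest.fixture(scope="session")
def ddi_results():
    """The full ten-victim interaction table (shared, ~1 s)."""
    return ddi_table()
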