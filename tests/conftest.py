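import logging

import pytest

from elasmobarcode import SimConfig, Taxonomy, generate_study, packaged_sample_table

logging.getLogger("elasmobarcode").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sample_table():
    return packaged_sample_table()


@pytest.fixture(scope="session")
def taxonomy():
    return Taxonomy.packaged()


@pytest.fixture(scope="session")
def clean_study():
    """Default-shape synthetic study without planted events."""
    cfg = SimConfig(misidentified_rate=0.0, novel_rate=0.0,
                    cryptic_rate=0.0, ambiguous_rate=0.0)
    return generate_study(cfg, seed=20230309)


@pytest.fixture(scope="session")
def eventful_study():
    """Default synthetic study including planted events."""
    return generate_study(seed=20230309)
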