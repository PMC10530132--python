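import pytest

from pelletopt import (
    ResponseSet,
    load_fixture,
    run_screening,
    sn_level_table,
    taguchi_anova,
)


@pytest.fixture(scope="session")
def pb_fixture():
    """Embedded screening design + per-trial DCW outcomes."""
    return load_fixture("table3")


@pytest.fixture(scope="session")
def pb_report(pb_fixture):
    """Full screening analysis of the embedded DCW means."""
    rs = ResponseSet.from_means(pb_fixture["design"].trials, pb_fixture["means"])
    return run_screening(pb_fixture["design"], rs, alpha=0.05,
                         dummy_symbol=pb_fixture["dummy"])


@pytest.fixture(scope="session")
def l9_fixture():
    """Embedded L9 design + per-trial biomass and S/N."""
    return load_fixture("table4")


@pytest.fixture(scope="session")
def l9_sn_table(l9_fixture):
    return sn_level_table(l9_fixture["design"], l9_fixture["sn"])


@pytest.fixture(scope="session")
def l9_anova(l9_sn_table):
    return taguchi_anova(l9_sn_table)
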