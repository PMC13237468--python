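import numpy as np
import pandas as pd
import pytest

from mhmcf import SimulationConfig, default_roles, simulate, split_visible


@pytest.fixture(scope="session")
def roles():
    return default_roles()


@pytest.fixture(scope="session")
def survey_default():
    """One default-size synthetic survey (with hidden truth columns)."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def prepared_default(survey_default):
    """Visible table with MHM complete (missing rows imputed)."""
    from mhmcf import prepare_table

    visible, _ = split_visible(survey_default)
    table, _, _, _ = prepare_table(visible)
    return table


def make_complete_table(seed=0, n=5000, **overrides):
    """Synthetic table with no missingness, MHM as int, truth attached."""
    cfg = SimulationConfig(seed=seed, n_individuals=n, missing_rate=0.0,
                           **overrides)
    table = simulate(cfg)
    table["mhm"] = table["mhm"].astype(int)
    return table, cfg
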