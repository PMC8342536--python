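import dataclasses

import numpy as np
import pandas as pd
import pytest

from glycodiff import simulate as sim


@pytest.fixture(scope="session")
def minimal_cohort():
    """Small deterministic cohort shared by smoke tests."""
    config = dataclasses.replace(sim.scenario_presets()["minimal"], seed=11)
    return sim.generate_cohort(config)


@pytest.fixture(scope="session")
def paper_like_cohort():
    """Study-sized cohort with the full spiked effect set."""
    config = dataclasses.replace(sim.scenario_presets()["paper-like"], seed=11)
    return sim.generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_glyco_records(rows):
    """Build a long quant table from (sample, protein, site, glycan, rt, auc)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "protein", "glycosite", "glycan", "rt", "auc"]
    )
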