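import pytest

import dietcalib as dc
from dietcalib.config import SimulationConfig


@pytest.fixture(scope="session")
def default_tables():
    """One default synthetic cohort (n=450), shared across read-only tests."""
    return dc.simulate_cohort(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def analysis(default_tables):
    return dc.build_analysis_table(default_tables)


@pytest.fixture(scope="session")
def big_cohort():
    """A 10,000-participant cohort for law-of-large-numbers checks."""
    cfg = SimulationConfig()
    cfg.cohort.n_participants = 10_000
    parts = dc.generate_participants(cfg.cohort, seed=5)
    psy = dc.generate_psychosocial(parts, cfg.cohort, seed=5)
    return cfg, parts, psy
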