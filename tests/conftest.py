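"""Shared fixtures: a small simulated cohort reused across test modules."""

import pytest

from ranabias.simulate import SimConfig, simulate_expression


@pytest.fixture(scope="session")
def cohort():
    """A 600-gene synthetic cohort with the default study design."""
    cfg = SimConfig(n_genes=600, seed=7)
    cm, samples, truth = simulate_expression(cfg)
    return cfg, cm, samples, truth
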