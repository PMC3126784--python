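"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pytest

import chlorosmall as cs


@pytest.fixture(scope="session")
def default_sim():
    """Default simulation (50k reads/condition) plus full analysis."""
    cfg = cs.default_config(seed=7)
    res = cs.generate_libraries(cfg)
    g = res.genome
    out = cs.run_analysis(
        res.reads,
        [g.chloroplast, g.other_chloroplast, g.nuclear],
        g.features,
        adapter=cfg.adapter,
        reference=cfg.reference,
        treatment=cfg.treatment,
    )
    return cfg, res, out


@pytest.fixture(scope="session")
def scenario_sim():
    """Heat-response scenario preset run end-to-end."""
    cfg = cs.paper_scenario(seed=101)
    res = cs.generate_libraries(cfg)
    g = res.genome
    out = cs.run_analysis(
        res.reads,
        [g.chloroplast, g.other_chloroplast, g.nuclear],
        g.features,
        adapter=cfg.adapter,
        reference=cfg.reference,
        treatment=cfg.treatment,
    )
    return cfg, res, out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
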