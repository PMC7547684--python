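import pytest

from epilnc.simulate import (
    SimulationConfig,
    simulate_celllines,
    simulate_expression,
    simulate_methylation_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated tumor/normal cohort at the default study conditions."""
    cfg = SimulationConfig(seed=11)
    beta, groups, sites, genes, truth = simulate_methylation_cohort(cfg)
    expr = simulate_expression(truth, cfg)
    return {
        "config": cfg,
        "beta": beta,
        "groups": groups,
        "sites": sites,
        "genes": genes,
        "truth": truth,
        "expr": expr,
    }


@pytest.fixture(scope="session")
def default_celllines(default_cohort):
    beta, expr = simulate_celllines(default_cohort["truth"], default_cohort["config"])
    return beta, expr
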