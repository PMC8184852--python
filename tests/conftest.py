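"""Shared simulation fixtures.

The heavy simulated datasets are session-scoped so the calibration,
recovery and property tests all reuse one realization instead of
re-simulating per test.  Seeds are fixed arbitrary constants.
"""

import pytest

from cisplast import pipeline
from cisplast.simdata import MODES, SimConfig, simulate_experiment

NULL_PROPORTIONS = {m: (1.0 if m == "none" else 0.0) for m in MODES}


@pytest.fixture(scope="session")
def sim_null():
    """2000 fully-null genes, allele overdispersion rho = 0.02, no bias."""
    cfg = SimConfig(
        n_genes=2000,
        seed=101,
        bb_overdispersion=0.02,
        mapping_bias_sd=0.0,
        mode_proportions=dict(NULL_PROPORTIONS),
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def sim_bias():
    """2000 null genes with planted mapping bias (SD 0.5 log2 odds)."""
    cfg = SimConfig(
        n_genes=2000,
        seed=102,
        bb_overdispersion=0.02,
        mapping_bias_sd=0.5,
        mode_proportions=dict(NULL_PROPORTIONS),
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def effects_bundle():
    """Full pipeline run on 2000 genes with planted effects (1.5 log2)."""
    cfg = SimConfig(n_genes=2000, seed=103, effect_log2=1.5, mean_depth=200.0)
    return pipeline.run_synthetic(cfg)


@pytest.fixture(scope="session")
def null_fit(sim_null):
    from cisplast import expression

    em, _, _ = sim_null
    return expression.fit_nested_model(em)


@pytest.fixture(scope="session")
def null_ase(sim_null):
    from cisplast import ase

    _, act, _ = sim_null
    norm, _ = ase.normalize_alleles(act)
    return ase.test_ase(norm, "hybrid1")


@pytest.fixture(scope="session")
def bias_ase(sim_bias):
    from cisplast import ase

    _, act, _ = sim_bias
    norm, _ = ase.normalize_alleles(act)
    return ase.test_ase(norm, "hybrid1")
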