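"""Shared fixtures: the seeded planted-structure bundle and one full
pipeline run at desk scale, shared session-wide because the null-ensemble
stages dominate runtime."""

from __future__ import annotations

import pytest

from comorbnet.community import ModularityParams
from comorbnet.pipeline import PipelineConfig, run_pipeline
from comorbnet.synthetic import SimulationConfig, simulate_bundle

#: the default study-condition fixture (200 genes, 4 planted modules,
#: p_in=0.4, p_out=0.01, phenotype signal-to-noise 10)
FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def bundle():
    return simulate_bundle(SimulationConfig(seed=FIXTURE_SEED))


def pipeline_config(seed: int = FIXTURE_SEED, **overrides) -> PipelineConfig:
    defaults = dict(
        simulate=SimulationConfig(seed=seed),
        modularity=ModularityParams(n_restarts=40, seed=seed),
        overlap_trials=1000,
        nmi_trials=200,
        enrichment_trials=1000,
        seed=seed,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def pipeline_result():
    return run_pipeline(pipeline_config())


def small_pipeline_config(seed: int = 3, **overrides) -> PipelineConfig:
    """A miniature configuration for fast smoke/determinism checks."""
    defaults = dict(
        simulate=SimulationConfig(n_genes=60, n_terms=60, terms_per_module=5, seed=seed),
        modularity=ModularityParams(n_restarts=5, seed=seed),
        overlap_trials=50,
        nmi_trials=20,
        enrichment_trials=150,
        n_shuffles=200,
        rank=2,
        seed=seed,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)
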