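import logging

import pytest

from mirscreen.pipeline import PipelineConfig, run_pipeline
from mirscreen.simulate import SimulationConfig, simulate_cohort

logging.getLogger("mirscreen").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort, shared across tests."""
    return simulate_cohort(SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run, shared across tests."""
    return run_pipeline(PipelineConfig(simulation=SimulationConfig(rng_seed=11)))
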