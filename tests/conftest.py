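import pytest

from lncsig import (
    PipelineConfig,
    SimulationConfig,
    generate_annotation,
    generate_term_map,
    simulate_cohort,
    simulate_timecourse,
)
from lncsig.pipeline import run_discovery


@pytest.fixture(scope="session")
def sim_cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def pipe_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def annotation(sim_cfg):
    return generate_annotation(sim_cfg)


@pytest.fixture(scope="session")
def timecourse(annotation, sim_cfg):
    return simulate_timecourse(annotation, sim_cfg)


@pytest.fixture(scope="session")
def cohort_data(annotation, sim_cfg):
    return simulate_cohort(annotation, sim_cfg)


@pytest.fixture(scope="session")
def termmap(annotation, sim_cfg):
    return generate_term_map(annotation, sim_cfg)


@pytest.fixture(scope="session")
def discovery(timecourse, annotation, termmap, pipe_cfg):
    counts, _ = timecourse
    return run_discovery(counts, annotation, termmap, pipe_cfg, seed=1)
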