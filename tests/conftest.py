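import pytest

from b12screen.pipeline import run_pipeline
from b12screen.registry import PipelineConfig, default_registry
from b12screen.simulate import (SimulationSpec, score_pipeline,
                                simulate_cohort)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 30 species, 6 families, loss 0.3,
    hgt 0.05, contamination 0.05, dropout 0.2, seed 1."""
    return simulate_cohort(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_report(default_cohort):
    """One full pipeline run over the default cohort, shared by the
    end-to-end tests."""
    c = default_cohort
    return run_pipeline(PipelineConfig(random_seed=1), c.registry,
                        c.libraries, c.manifests, c.validation_db,
                        reference_homologues=c.bacterial_refs)


@pytest.fixture(scope="session")
def pipeline_metrics(default_cohort, pipeline_report):
    return score_pipeline(default_cohort, pipeline_report.matrix,
                          pipeline_report.statuses)
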