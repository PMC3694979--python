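import numpy as np
import pytest

from ssirs.io import PipelineConfig, SimulateBlock
from ssirs.pipeline import run_pipeline
from ssirs.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest heterogeneity-rich cohort shared by read-only tests."""
    cfg = default_config(n_records=6000, seed=11, n_groups=60)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run reused by derivation/scoring/evaluation tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        outdir=str(outdir), seed=3,
        simulate=SimulateBlock(n_records=12_000, n_groups=120))
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
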