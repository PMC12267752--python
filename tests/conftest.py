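import pytest

from ventswitch.pipeline import RunConfig, run_pipeline
from ventswitch.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_tables():
    """A small default-condition cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_patients=150, seed=42))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on a small synthetic cohort."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(cohort=CohortConfig(n_patients=150, seed=42), out_dir=str(out), seed=42)
    return cfg, run_pipeline(cfg)
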