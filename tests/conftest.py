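import numpy as np
import pytest

from glompath import phantom as ph
from glompath.pipeline import RunConfig, run_bfe


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """Full default pipeline run on a 45-patient phantom cohort.

    Shared across the end-to-end checks (CV accuracy, Dice, feature
    recovery, patient-level aggregation) so the cohort is generated and
    featurized only once per session.
    """
    out = tmp_path_factory.mktemp("cohort_run")
    return run_bfe(RunConfig(out_dir=str(out)))


@pytest.fixture(scope="session")
def mn_phantom():
    """One deterministic MN phantom at a small canvas for unit tests."""
    profile = ph.default_profiles(256)["MN"]
    return ph.generate_glomerulus(profile, 42)


@pytest.fixture()
def rng():
    # fresh deterministic stream per test: results don't depend on test order
    return np.random.default_rng(1234)
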