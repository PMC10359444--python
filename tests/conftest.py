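import numpy as np
import pandas as pd
import pytest

from dkd_arules import CohortProfile, simulate_cohort


@pytest.fixture(scope="session")
def general_cohort():
    """A small general-profile cohort reused by read-only tests."""
    profile = CohortProfile.general(n_subjects=800, seed=42)
    return simulate_cohort(profile)


@pytest.fixture(scope="session")
def mined_run(tmp_path_factory):
    """One full pipeline run (all schemes) shared across read-only tests."""
    from dkd_arules import run_pipeline

    outdir = tmp_path_factory.mktemp("mined_run")
    manifest = run_pipeline(
        {
            "cohort": {"kind": "general", "profile": {"n_subjects": 2000}},
            "output_dir": str(outdir),
            "seed": 42,
        }
    )
    rules = pd.read_csv(outdir / "rules.csv")
    exposure = pd.read_csv(outdir / "exposure.csv")
    return {"outdir": outdir, "manifest": manifest, "rules": rules, "exposure": exposure}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
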