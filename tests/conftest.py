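"""Shared fixtures: tiny phantom cohorts and the (expensive) desk-scale run."""

import numpy as np
import pytest

from hepanomaly import PhantomParams, generate_cohort, pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """12 slices / 4 subjects, all lesioned, 64 px."""
    return generate_cohort(4, 3, 1.0, PhantomParams(seed=7))


@pytest.fixture(scope="session")
def healthy_cohort():
    return generate_cohort(4, 3, 0.0, PhantomParams(seed=11))


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """The full desk-scale pipeline run shared by the end-to-end tests.

    64 px phantoms, 300 healthy DDPM training slices, T=50 with r=4
    resampling, grouped 5-fold evaluation — executed once per session.
    """
    run_dir = tmp_path_factory.mktemp("desk_run")
    cfg = pipeline.desk_scale_config(seed=1)
    return pipeline.run_pipeline(cfg, run_dir)
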