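import dataclasses

import numpy as np
import pytest

import bepopk as bp


@pytest.fixture
def pop():
    """Published bepotastine population parameters (package defaults)."""
    return bp.PopulationParams()


@pytest.fixture
def typical_adult():
    """Typical 70 kg adult structural parameters."""
    return bp.StructuralParams(ka=4.21, cl=28.0, v=103.0, alag=0.27)


@pytest.fixture
def no_variability_pop():
    """Population model with IIV and residual error switched off (the
    additive variance is kept microscopic so residual variances stay valid)."""
    base = bp.PopulationParams()
    return dataclasses.replace(
        base,
        iiv_cv={k: 0.0 for k in base.iiv_cv},
        corr_cl_v=0.0,
        corr_cl_alag=0.0,
        sigma_prop=0.0,
        additive_error=1e-12,
    )


@pytest.fixture(scope="session")
def two_study_dataset():
    """One seeded two-study dataset at the published parameter values,
    LLOQ-filtered, shared by the estimation and diagnostics tests."""
    pop = bp.PopulationParams()
    tbl = bp.simulate_two_study_dataset(pop, np.random.default_rng(20240227))
    return bp.apply_lloq_filter(tbl)
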