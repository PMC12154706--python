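"""Shared fixtures: small simulated cohorts and model specifications."""

import numpy as np
import pytest

from nccjoint.datatypes import JointModelSpec, ParameterSet
from nccjoint.estimation import ModelData
from nccjoint.sampling import draw_controls, select_cases_and_censor
from nccjoint.simulate import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def replication_params() -> ParameterSet:
    """True replication-condition parameters on the fitted scale."""
    return ParameterSet(
        gamma=[0.1], log_disp=0.0, log_theta=0.5 * np.log(2.0),
        beta=[0.0, 0.0], alpha=[[-0.2], [-0.2]], log_xi=[[-5.0], [-4.0]],
    )


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study: observed cohort, NCC sample, spec, data.

    300 subjects, 30 cases, 1 control per case; same generating process as
    the replication conditions otherwise.
    """
    config = SimConfig(N=300, n_cases_target=30, seed=42)
    cohort = simulate_cohort(config)
    case_ids, censor_time, observed = select_cases_and_censor(cohort, 30)
    sample = draw_controls(observed, case_ids, 1, np.random.default_rng(7))
    spec = JointModelSpec(K=2, survival_covariate_names=("X2",),
                          baseline_knots=[0.0, censor_time])
    data = ModelData(observed, spec)
    return {"config": config, "observed": observed, "sample": sample,
            "spec": spec, "data": data, "censor_time": censor_time}
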