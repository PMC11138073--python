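import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import qmcea

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

warnings.filterwarnings("ignore", message="missingness pattern is not monotone")


@pytest.fixture(scope="session")
def complete_trial():
    """A SHIFT-scale complete (pre-missingness) fixture dataset."""
    spec = qmcea.CohortSpec(seed=11)
    roster = qmcea.generate_cohort(spec)
    return qmcea.generate_trajectories(roster, qmcea.TrajectoryParams(), spec.seed)


@pytest.fixture(scope="session")
def observed_trial(complete_trial):
    """The same fixture after dropout, record gaps and censoring."""
    return qmcea.apply_missingness(complete_trial, qmcea.TrajectoryParams(), 11)


@pytest.fixture(scope="session")
def small_suite():
    """A pooled model suite fitted on a moderate fixture (fast shared object)."""
    spec = qmcea.CohortSpec(n_ft=150, n_tau=150, seed=7)
    data = qmcea.simulate_trial(spec)
    imputed = qmcea.multiple_impute(data, qmcea.ImputationSpec(m=3, seed=7))
    return qmcea.fit_suite(imputed, alpha=0.05)


def minimal_frame(n, outcome, values, arm="TAU", cycle=0):
    """A one-cycle stacked frame with reference-level covariates."""
    df = pd.DataFrame({
        "patient_id": np.arange(n), "arm": arm, "cycle": cycle,
        outcome: np.asarray(values, dtype=float),
    })
    for cov in qmcea.synthetic.COVARIATES:
        df[cov] = 0
    return df
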