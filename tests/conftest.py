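import numpy as np
import pandas as pd
import pytest

from phenoyield.growth import GompertzParams, LogisticParams, SigmoidFit
from phenoyield.simulate import (
    TrialDesign,
    YieldModelTruth,
    sample_genotype_truth,
    simulate_trial,
)

SCHEDULE_12 = tuple(range(14, 130, 10))


@pytest.fixture(scope="session")
def small_design() -> TrialDesign:
    """8 genotypes x 2 reps, one year, 12 flights, no missingness."""
    return TrialDesign(
        n_genotypes=8, n_reps=2, dap_schedules={"2021": SCHEDULE_12}, missing_rate=0.0
    )


@pytest.fixture(scope="session")
def small_trial(small_design):
    truth = sample_genotype_truth(small_design, seed=7)
    return simulate_trial(small_design, truth, YieldModelTruth(), seed=7)


@pytest.fixture(scope="session")
def gompertz_fit() -> SigmoidFit:
    """The reference Gompertz curve A=1, b=5, c=0.1 over a 0..60 DAP window."""
    return SigmoidFit(
        family="gompertz",
        params=GompertzParams(1.0, 5.0, 0.1),
        rss=0.0,
        r2_fit=1.0,
        converged=True,
        window=(0.0, 60.0),
    )


@pytest.fixture(scope="session")
def logistic_fit() -> SigmoidFit:
    return SigmoidFit(
        family="logistic",
        params=LogisticParams(asymptote=0.95, initial=0.02, rate=0.15),
        rss=0.0,
        r2_fit=1.0,
        converged=True,
        window=(0.0, 90.0),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
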