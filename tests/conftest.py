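import numpy as np
import pytest

from ratespec.datatypes import StationaryProduct, TrajectoryEnsemble
from ratespec.reaction_times import SingleExponential
from ratespec.simulate import SimRun, simulate_renewal_birth_death


@pytest.fixture(scope="session")
def poisson_ensemble() -> TrajectoryEnsemble:
    """Poisson birth-death, creation rate 2*gamma with gamma = 1.

    Shared across estimator tests: the stationary count is Poisson with
    mean 2 and the number spectrum is the Lorentzian 4/(omega^2 + 1).
    """
    run = SimRun(seed=101, n_traj=200, t_total=220.0, dt_record=0.05, burn_in=20.0)
    return simulate_renewal_birth_death(SingleExponential(2.0), gamma=1.0, run=run)


@pytest.fixture(scope="session")
def poisson_stat(poisson_ensemble) -> StationaryProduct:
    return StationaryProduct.from_mean_count(
        float(poisson_ensemble.counts.mean()), gamma=1.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
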