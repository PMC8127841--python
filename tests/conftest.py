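import numpy as np
import pytest

from mcrc_cea import Strategy, TransitionParams, default_parameters, mcmc_fit
from mcrc_cea.km_reconstruct import PseudoIPD
from mcrc_cea.synthetic_trial import observed_endpoint, simulate_cohort


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def kras_truth(params):
    return {
        arm: TransitionParams.from_mapping(tp)
        for arm, tp in params.populations["kras_wt"].items()
    }


def simulate_ipd(truth, n, seed, max_follow_up=312, accrual=78):
    """Simulated cohort -> (PFS, OS) pseudo-data, bypassing reconstruction."""
    paths = simulate_cohort(truth, n, max_follow_up, accrual_weeks=accrual, seed=seed)
    t_p, e_p = observed_endpoint(paths, "PFS")
    t_o, e_o = observed_endpoint(paths, "OS")
    return (
        PseudoIPD(t_p, e_p, endpoint="PFS"),
        PseudoIPD(t_o, e_o, endpoint="OS"),
    )


@pytest.fixture(scope="session")
def fitted_strategies(params, kras_truth):
    """Two strategies with short but converged posterior chains (2,000 draws)."""
    strategies = []
    for i, (arm_name, arm) in enumerate(params.arms.items()):
        pfs, os_ = simulate_ipd(kras_truth[arm_name], 400, seed=11 + i)
        draws = mcmc_fit(
            pfs, os_, iterations=5_200, burn_in=1_200, thinning=2, seed=21 + i
        )
        strategies.append(Strategy(arm=arm, draws=draws))
    return tuple(strategies)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
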