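import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def system():
    from gpvalue import DEFAULT_SYSTEM

    return DEFAULT_SYSTEM


@pytest.fixture(scope="session")
def roughness(system):
    from gpvalue import RoughnessParams

    return RoughnessParams.default(system)


@pytest.fixture(scope="session")
def desk_fit():
    """One shared desk-scale synthetic donor dataset and crude fit."""
    import gpvalue as g
    from gpvalue.synthetic_data import SimulationScenario, random_states, simulate

    rng = np.random.default_rng(42)
    donor_states = random_states(30, rng)
    target_states = random_states(12, rng)
    scenario = SimulationScenario(
        donor_states,
        target_states,
        n_donor_respondents=60,
        n_target_respondents=20,
        donor_quota=8,
        target_quota=6,
        seed=42,
    )
    truth, data, info = simulate(scenario)
    config = g.McmcConfig(n_iterations=3000, n_burnin=1000, thin=1, seed=7)
    draws = g.fit_crude(data["donor"], config)
    return {
        "scenario": scenario,
        "truth": truth,
        "data": data,
        "info": info,
        "config": config,
        "draws": draws,
    }
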