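import numpy as np
import pytest

import movescape as ms

# movement regimes used as generating truth throughout the suite: per-state
# step-length mean/SD in meters and long-run time budgets
SUBURBAN_2STATE = {
    "step_means": [7.6, 319.0],
    "step_sds": [7.2, 256.0],
    "budget": [0.58, 0.42],
    "kappas": [0.5, 1.5],
}
NATURAL_2STATE = {
    "step_means": [7.4, 306.0],
    "step_sds": [8.3, 238.0],
    "budget": [0.57, 0.43],
    "kappas": [0.5, 1.5],
}
URBAN_3STATE = {
    "step_means": [7.5, 122.0, 625.0],
    "step_sds": [7.2, 114.0, 385.0],
    "budget": [0.62, 0.21, 0.20],
    "kappas": [0.5, 0.7, 2.0],
}


def regime_config(regime, n_steps, seed, zero_mass=0.01, switching=0.3, budget=None):
    """SimulationConfig for one of the movement regimes above."""
    K = len(regime["step_means"])
    budget = np.asarray(regime["budget"] if budget is None else budget, float)
    return ms.SimulationConfig(
        n_states=K,
        step_means=regime["step_means"],
        step_sds=regime["step_sds"],
        zero_mass=np.full(K, zero_mass),
        angle_means=[np.pi] * (K - 1) + [0.0],
        kappas=regime["kappas"],
        tmat=ms.transition_matrix_for_stationary(budget / budget.sum(), switching),
        n_steps=n_steps,
        seed=seed,
    )


@pytest.fixture(scope="session")
def suburban_series_5000():
    """5,000 steps simulated from the suburban 2-state regime."""
    track = ms.simulate_hmm_track(regime_config(SUBURBAN_2STATE, 5000, seed=1))
    return ms.steps_and_angles(track), track


@pytest.fixture(scope="session")
def suburban_fit_2state(suburban_series_5000):
    series, _ = suburban_series_5000
    return ms.fit_hmm([series], 2)


@pytest.fixture(scope="session")
def urban_series_5000():
    """5,000 steps simulated from the highly urbanized 3-state regime."""
    track = ms.simulate_hmm_track(regime_config(URBAN_3STATE, 5000, seed=1))
    return ms.steps_and_angles(track), track


@pytest.fixture(scope="session")
def urban_fit_3state(urban_series_5000):
    series, _ = urban_series_5000
    return ms.fit_hmm([series], 3)
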