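import numpy as np
import pytest

from valudyn.ddm import DDMParameters, code_attributes, simulate_trials
from valudyn.synth import CohortConfig, generate_cohort

#: worked-example parameter set used throughout the docs and tests
EXAMPLE_PARAMS = DDMParameters(
    w_tastiness=0.7, w_healthiness=0.1, val_const=0.5,
    threshold=0.9, sp_bias=0.45, ndt=0.462,
)


@pytest.fixture(scope="session")
def small_cohort():
    """6-subject cohort at the study's trial counts (generated once)."""
    cfg = CohortConfig(n_subjects=6)
    params, trials = generate_cohort(cfg, seed=101)
    return params, trials


@pytest.fixture(scope="session")
def example_trialset():
    """540 trials simulated from the worked-example parameters."""
    rng = np.random.default_rng(11)
    taste = rng.integers(1, 7, 540)
    health = rng.integers(1, 7, 540)
    t_c, h_c = code_attributes(taste, health)
    choice, rt = simulate_trials(EXAMPLE_PARAMS, t_c, h_c, dt=1e-3, horizon=4.0, rng=rng)
    return {"taste": taste, "health": health, "t_c": t_c, "h_c": h_c, "choice": choice, "rt": rt}


@pytest.fixture(scope="session")
def detection_runs():
    """The 20-seed end-to-end detection experiment (shared by the detection
    and template-discrimination acceptance tests)."""
    from valudyn.experiments import detection_experiment

    return detection_experiment(seed=2024, n_seeds=20)
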