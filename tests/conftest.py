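import numpy as np
import pytest

from criskit import Cohort, Covariate, Schema
from criskit.simulate import CauseSpec, SimSpec, simulate_cause_specific


@pytest.fixture
def toy_cohort():
    """Three subjects: cause-1 at t=1, cause-2 at t=2, censored at t=3."""
    return Cohort([1, 2, 3], [1.0, 2.0, 3.0], [1, 2, 0], n_causes=2)


@pytest.fixture
def sex_age_cohort():
    """Small cohort with a binary and a 3-level categorical covariate."""
    schema = Schema(
        (
            Covariate("sex", kind="categorical", levels=("female", "male")),
            Covariate("agegrp", kind="categorical", levels=("<40", "40-60", ">60")),
        )
    )
    rng = np.random.default_rng(1)
    n = 40
    times = rng.exponential(5.0, n).round(3) + 0.001
    events = rng.integers(0, 3, n)
    if not (events == 1).any():
        events[0] = 1
    if not (events == 2).any():
        events[1] = 2
    sex = np.where(rng.random(n) < 0.5, "male", "female").astype(object)
    age = rng.choice(np.array(["<40", "40-60", ">60"], dtype=object), n)
    return Cohort(
        np.arange(n), times, events, {"sex": sex, "agegrp": age}, n_causes=2, schema=schema
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """Medium simulated two-risk cohort with covariates, session-cached."""
    spec = SimSpec(
        n=500,
        causes=(CauseSpec(0.05, (0.4, 0.2)), CauseSpec(0.1, (-0.3, 0.5))),
        covariates={"male": ("bernoulli", 0.5), "x": ("normal", 0.0, 1.0)},
        censor_rate=0.07,
        seed=3,
    )
    return simulate_cause_specific(spec)
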