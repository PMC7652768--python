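import numpy as np
import pytest
from hypothesis import settings

from prmix import PriorSpec, SamplerConfig
from prmix.cohort import Cohort, CohortArrays, MinerRecord
from prmix.mixture import MixtureState, stick_breaking
from prmix.synthetic import simulate_cohort, toy_truth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def prior() -> PriorSpec:
    return PriorSpec()


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-cluster cohort shared by sampler-level tests."""
    truth = toy_truth(n=200, n_clusters=2, seed=11)
    cohort, labels = simulate_cohort(truth)
    return truth, cohort, labels


@pytest.fixture(scope="session")
def small_arrays(small_cohort) -> CohortArrays:
    _, cohort, _ = small_cohort
    return CohortArrays(cohort)


def make_record(
    y_years=62.0, delta=1, entry_years=25.0, x=(40.0, 80.0, 2.0),
    age_first=26.0, job=2, mine=2, dur=3,
) -> MinerRecord:
    d = 365.25
    return MinerRecord(
        y=y_years * d, delta=delta, entry_age=entry_years * d,
        x_radon=x[0], x_gamma=x[1], x_dust=x[2],
        age_first_exposure=age_first, job=job, mine=mine, duration_class=dur,
    )


def make_state(arrays: CohortArrays, C: int, seed: int, prior: PriorSpec) -> MixtureState:
    """A random admissible mixture state over ``arrays``."""
    rng = np.random.default_rng(seed)
    V = rng.uniform(0.2, 0.8, size=max(C - 1, 0))
    lam = prior.lam_shapes / prior.lam_rates * rng.uniform(0.5, 2.0, size=4)
    return MixtureState(
        beta=rng.uniform(-0.5, 3.0, size=C),
        mu=arrays.logx.mean(axis=0) + rng.normal(0, 1, size=(C, 4)),
        sigma=rng.uniform(0.3, 2.0, size=(C, 4)),
        p_job=rng.dirichlet(np.ones(5), size=C),
        p_mine=rng.dirichlet(np.ones(2), size=C),
        p_dur=rng.dirichlet(np.ones(4), size=C),
        V=V,
        phi=stick_breaking(V, C) if C > 1 else np.ones(1),
        alpha=float(rng.uniform(0.5, 5.0)),
        lam=lam,
        alloc=rng.integers(C, size=arrays.m),
    )
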