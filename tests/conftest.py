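import numpy as np
import pytest

from astailor.simulate import (
    Cohort,
    ObservedSubject,
    ScenarioConfig,
    SubjectLatent,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def scenario1() -> ScenarioConfig:
    return ScenarioConfig.for_scenario(1)


@pytest.fixture(scope="session")
def cohort500(scenario1) -> Cohort:
    return simulate_cohort(500, scenario1, seed=42)


@pytest.fixture(scope="session")
def cohort2000(scenario1) -> Cohort:
    return simulate_cohort(2000, scenario1, seed=7)


def make_subject(times, results, p=4, cov_times=(), rng=None):
    """Hand-built observed subject with deterministic covariates."""
    rng = rng or np.random.default_rng(0)
    all_times = list(times) + [t for t in cov_times if t not in times]
    covs = {float(t): rng.normal(size=p) for t in all_times}
    return ObservedSubject(
        biopsy_times=np.asarray(times, dtype=float),
        results=np.asarray(results, dtype=int),
        covariates_at=covs,
        dropped_out=bool(list(results) and results[-1] == 1),
    )


@pytest.fixture
def toy_cohort():
    """Five hand-specified subjects around landmark s=30, tau=25."""
    rng = np.random.default_rng(3)
    subjects = [
        make_subject([30.0, 55.0], [0, 1], cov_times=[30.0], rng=rng),
        make_subject([28.0, 60.0, 80.0], [0, 0, 0], cov_times=[30.0], rng=rng),
        make_subject([50.0], [1], cov_times=[30.0], rng=rng),
        make_subject([33.0, 57.0], [0, 0], cov_times=[30.0], rng=rng),
        make_subject([20.0], [0], cov_times=[30.0], rng=rng),
    ]
    return Cohort(subjects=subjects)
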