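"""Synthetic active-surveillance cohorts with interval-censored progression.

The generator emulates a prostate-cancer-style surveillance study:

* Each subject carries p latent covariate trajectories, linear in
  log-time, ``W_l(t) = a_{0,l} + a_{1,l} log(t/nu)``, with the per-process
  slope pair drawn from a bivariate normal. Observed covariates add
  independent Gaussian measurement error.
* Progression time ``T`` follows a Weibull-type proportional-hazards model
  driven by trajectories 2..4, with an optional quadratic (non-linear)
  term controlled by ``r_nl`` (zero in scenario 1, 0.1 in scenario 2).
  ``T`` is sampled by a closed-form transform of a standard exponential:

      T = entry + nu * [ T~ * gamma / nu_shape
                         * exp(-a_0^T beta - r_nl (a_{0,1}+a_{0,2})^2) ]^{1/gamma},
      gamma = nu_shape + a_1^T beta + r_nl (a_{1,1}+a_{1,2})^2.

* Lost-to-follow-up censoring ``C`` is uniform on [censor_lo, censor_hi].
* Biopsies are scheduled at random: the first uniform on
  [entry, 3 T_gap], each subsequent gap uniform on [T_gap, 3 T_gap],
  stopping once the previous time plus T_gap exceeds the horizon.
* A biopsy at N_k is observed only if C > N_k (censoring is terminal) and
  it is not missed (probability ``miss_prob`` per biopsy); the subject
  drops out immediately after the first observed positive biopsy.

Oracle truth (T, C and the latent slopes) is retained alongside the
observed records so estimators can be benchmarked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ScenarioConfig",
    "SubjectLatent",
    "ObservedSubject",
    "Cohort",
    "draw_subject",
    "draw_latents",
    "event_time_transform",
    "covariate_value",
    "draw_biopsy_schedule",
    "assemble_observed",
    "simulate_cohort",
    "subcohort",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative constants for the simulation scenarios.

    ``scenario`` 1 uses a log-linear hazard (``r_nl = 0``); scenario 2 adds
    the quadratic term (``r_nl = 0.1``). All times are in months.
    """

    scenario: int = 1
    p: int = 4
    slope_mean: tuple[float, float] = (-0.1, -0.1)
    slope_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (0.82**2, -0.005),
        (-0.005, 0.13**2),
    )
    meas_var: float = 0.1
    beta: tuple[float, ...] = (-0.7, 0.8, -1.3)  # applies to processes 2..4
    r_nl: float = 0.0
    nu: float = 30.0
    nu_scale: float = 15.0
    nu_shape: float = 1.4
    entry_offset: float = 12.0
    censor_lo: float = 12.0
    censor_hi: float = 150.0
    horizon: float = 150.0
    T_gap: float = 24.0
    miss_prob: float = 0.0
    dropout: bool = True
    landmarks: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0)
    tau: float = 24.0

    def __post_init__(self):
        if self.nu_shape <= 0:
            raise ValueError("nu_shape must be > 0")
        if not self.censor_lo < self.censor_hi:
            raise ValueError("censor_lo must be < censor_hi")
        if self.T_gap <= 0:
            raise ValueError("T_gap must be > 0")
        if not 0 <= self.miss_prob < 1:
            raise ValueError("miss_prob must be in [0, 1)")
        cov = np.asarray(self.slope_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("slope_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov)[0] <= 0:
            raise ValueError("slope_cov must be positive definite")
        if len(self.beta) != self.p - 1:
            raise ValueError("beta must have one entry per process l = 2..p")

    @classmethod
    def for_scenario(cls, scenario: int, **overrides) -> "ScenarioConfig":
        if scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        r_nl = 0.0 if scenario == 1 else 0.1
        return cls(scenario=scenario, r_nl=overrides.pop("r_nl", r_nl), **overrides)

    def with_(self, **overrides) -> "ScenarioConfig":
        return replace(self, **overrides)


@dataclass(frozen=True)
class SubjectLatent:
    """Oracle truth for one subject: slope pairs, event time, censoring time."""

    a0: np.ndarray  # length-p intercepts a_{0,l}
    a1: np.ndarray  # length-p log-time slopes a_{1,l}
    T_true: float
    C: float


@dataclass
class ObservedSubject:
    """The observed biopsy record after censoring, missingness and dropout.

    ``biopsy_times`` and ``results`` align; under dropout at most one result
    is positive and, if present, it is the last entry. ``covariates_at``
    maps measurement times (biopsy times and the landmark grid) to the
    noisy p-vector of covariates.
    """

    biopsy_times: np.ndarray
    results: np.ndarray
    covariates_at: dict[float, np.ndarray]
    dropped_out: bool = False

    @property
    def last_time(self) -> float:
        """Last observed biopsy time (0 if no biopsy was observed)."""
        return float(self.biopsy_times[-1]) if len(self.biopsy_times) else 0.0

    def adjacent_pairs(self):
        """Consecutive observed-biopsy pairs, prepending the baseline N_0 = 0.

        Yields (t_prev, t_curr, res_prev, res_curr); the confirmatory
        baseline biopsy at time 0 is negative by definition.
        """
        prev_t, prev_r = 0.0, 0
        for t, r in zip(self.biopsy_times, self.results):
            yield prev_t, float(t), prev_r, int(r)
            prev_t, prev_r = float(t), int(r)

    def neg_pos_pair(self):
        """The adjacent negative-positive pair bracketing T, if observed."""
        for t0, t1, r0, r1 in self.adjacent_pairs():
            if r0 == 0 and r1 == 1:
                return t0, t1
        return None

    def covariates_at_time(self, s: float) -> np.ndarray:
        """Most up-to-date covariate vector at time s (last value carried
        forward when no measurement falls exactly at s)."""
        if s in self.covariates_at:
            return self.covariates_at[s]
        times = sorted(self.covariates_at)
        if not times:
            raise KeyError("subject has no covariate measurements")
        past = [t for t in times if t <= s]
        return self.covariates_at[past[-1] if past else times[0]]


@dataclass
class Cohort:
    """A simulated or loaded cohort, optionally carrying oracle truth."""

    subjects: list[ObservedSubject]
    truth: list[SubjectLatent] | None = None
    seed: int | None = None
    config: ScenarioConfig | None = None

    def __post_init__(self):
        if self.truth is not None and len(self.truth) != len(self.subjects):
            raise ValueError("truth must align one-to-one with subjects")

    @property
    def n(self) -> int:
        return len(self.subjects)


def _beta_dot(config: ScenarioConfig, a: np.ndarray) -> np.ndarray:
    """a^T beta over processes l = 2..p; a has shape (..., p)."""
    beta = np.asarray(config.beta, dtype=float)
    return a[..., 1:] @ beta


def event_time_transform(config: ScenarioConfig, a0, a1, t_tilde):
    """Closed-form event time from a standard-exponential draw.

    Vectorized over leading axes of a0/a1 (shape (..., p)) and t_tilde.
    Returns (T, gamma); gamma must be positive for the transform to be a
    valid monotone map of t_tilde.
    """
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    t_tilde = np.asarray(t_tilde, dtype=float)
    r = config.r_nl
    gamma = config.nu_shape + _beta_dot(config, a1) + r * (a1[..., 0] + a1[..., 1]) ** 2
    bracket = (
        t_tilde
        / config.nu_shape
        * gamma
        * np.exp(-_beta_dot(config, a0) - r * (a0[..., 0] + a0[..., 1]) ** 2)
    )
    T = config.entry_offset + config.nu * bracket ** (1.0 / gamma)
    return T, gamma


_GAMMA_FLOOR = 1e-3
_MAX_RETRIES = 100


def draw_latents(config: ScenarioConfig, n: int, rng: np.random.Generator):
    """Vectorized draw of n subjects' latent truth.

    Returns (a0, a1, T, C) arrays of shapes (n, p), (n, p), (n,), (n,).
    Rows whose gamma falls at or below a small floor are redrawn (the
    closed-form transform degenerates); a config for which this keeps
    happening is rejected after a bounded number of rounds.
    """
    mean = np.asarray(config.slope_mean, dtype=float)
    L = np.linalg.cholesky(np.asarray(config.slope_cov, dtype=float))
    p = config.p

    def _draw(m):
        z = rng.standard_normal((m, p, 2))
        a = mean + z @ L.T  # (m, p, 2): per-process (a0, a1) pairs
        return a[..., 0], a[..., 1]

    a0, a1 = _draw(n)
    r = config.r_nl
    gamma = config.nu_shape + _beta_dot(config, a1) + r * (a1[:, 0] + a1[:, 1]) ** 2
    for _ in range(_MAX_RETRIES):
        bad = gamma <= _GAMMA_FLOOR
        if not bad.any():
            break
        b0, b1 = _draw(int(bad.sum()))
        a0[bad], a1[bad] = b0, b1
        gamma[bad] = (
            config.nu_shape + _beta_dot(config, b1) + r * (b1[:, 0] + b1[:, 1]) ** 2
        )
    else:
        raise ValueError(
            "degenerate config: gamma <= 0 persists after "
            f"{_MAX_RETRIES} resampling rounds"
        )
    t_tilde = rng.exponential(size=n)
    T, _ = event_time_transform(config, a0, a1, t_tilde)
    C = rng.uniform(config.censor_lo, config.censor_hi, size=n)
    return a0, a1, T, C


def draw_subject(config: ScenarioConfig, rng: np.random.Generator) -> SubjectLatent:
    """Draw one subject's latent slopes, event time and censoring time."""
    a0, a1, T, C = draw_latents(config, 1, rng)
    return SubjectLatent(a0=a0[0], a1=a1[0], T_true=float(T[0]), C=float(C[0]))


def covariate_value(
    config: ScenarioConfig,
    latent: SubjectLatent,
    l: int,
    t: float,
    with_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Covariate process l (0-based) at time t: W_l(t) plus optional noise."""
    if t <= 0:
        raise ValueError(f"covariate time must be positive, got {t}")
    w = latent.a0[l] + latent.a1[l] * np.log(t / config.nu)
    if with_noise:
        if rng is None:
            raise ValueError("rng required when with_noise=True")
        w = w + rng.normal(0.0, np.sqrt(config.meas_var))
    return float(w)


def _covariate_vector(
    config: ScenarioConfig,
    a0: np.ndarray,
    a1: np.ndarray,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    w = a0 + a1 * np.log(t / config.nu)
    return w + rng.normal(0.0, np.sqrt(config.meas_var), size=len(a0))


def draw_biopsy_schedule(
    config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random biopsy schedule: N_1 ~ U[entry, 3 T_gap], then gaps
    U[T_gap, 3 T_gap], stopping once the previous time plus T_gap exceeds
    the horizon."""
    g = config.T_gap
    first_hi = max(3.0 * g, config.entry_offset)
    times = [rng.uniform(config.entry_offset, first_hi)]
    while times[-1] + g <= config.horizon:
        times.append(rng.uniform(times[-1] + g, times[-1] + 3.0 * g))
    return np.asarray(times)


def assemble_observed(
    latent: SubjectLatent,
    schedule: Sequence[float],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> ObservedSubject:
    """Apply censoring, missingness and dropout to a biopsy schedule.

    Walks the schedule in order: censoring (C <= N_k) is terminal; a missed
    biopsy (probability miss_prob) is skipped but later ones may still be
    observed; after the first observed positive the subject drops out
    (unless the config disables dropout, a diagnostic mode in which
    positives keep accruing).
    """
    times: list[float] = []
    results: list[int] = []
    dropped = False
    for N in schedule:
        if latent.C <= N:  # zeta_k = 0: lost to follow-up, terminal
            break
        if config.miss_prob > 0 and rng.random() < config.miss_prob:
            continue  # delta_k = 0: this biopsy only
        delta = 1 if latent.T_true <= N else 0
        times.append(float(N))
        results.append(delta)
        if delta == 1 and config.dropout:
            dropped = True
            break
    covariates: dict[float, np.ndarray] = {}
    for t in times:
        covariates[t] = _covariate_vector(config, latent.a0, latent.a1, t, rng)
    for t in config.landmarks:
        t = float(t)
        if t not in covariates:
            covariates[t] = _covariate_vector(config, latent.a0, latent.a1, t, rng)
    return ObservedSubject(
        biopsy_times=np.asarray(times),
        results=np.asarray(results, dtype=int),
        covariates_at=covariates,
        dropped_out=dropped,
    )


def simulate_cohort(n: int, config: ScenarioConfig, seed: int) -> Cohort:
    """Simulate a cohort of n independent subjects; pure in (n, config, seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a0, a1, T, C = draw_latents(config, n, rng)
    subjects, truth = [], []
    for i in range(n):
        lat = SubjectLatent(a0=a0[i], a1=a1[i], T_true=float(T[i]), C=float(C[i]))
        schedule = draw_biopsy_schedule(config, rng)
        subjects.append(assemble_observed(lat, schedule, config, rng))
        truth.append(lat)
    return Cohort(subjects=subjects, truth=truth, seed=seed, config=config)


def subcohort(cohort: Cohort, indices) -> Cohort:
    """Subset a cohort by subject indices, keeping truth aligned."""
    indices = np.asarray(indices, dtype=int)
    return Cohort(
        subjects=[cohort.subjects[i] for i in indices],
        truth=None if cohort.truth is None else [cohort.truth[i] for i in indices],
        seed=cohort.seed,
        config=cohort.config,
    )
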