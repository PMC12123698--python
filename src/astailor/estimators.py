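"""Kernel estimators of time-varying TPR/TNR and the weighted-benefits value.

The setting: progression is only examined at biopsies, so the event time T
is interval-censored, and subjects leave the study immediately after the
first positive biopsy (progression-triggered dropout). Two nonparametric
estimators exploit the randomness of biopsy times:

* TNR at landmark s with horizon tau uses every observed *negative* biopsy:
  negatives remain observable after dropout never happens for them, so a
  one-dimensional kernel in the biopsy time around s + tau recovers the
  event-free population.

* TPR uses adjacent negative-positive biopsy pairs: the pair (N_(k), N_k)
  with results (0, 1) brackets T and is observed regardless of how many
  positive biopsies would have followed, so a two-dimensional kernel in
  (N_k - s - tau, N_(k) - s) recovers the population with s < T <= s + tau
  without dropout bias. The confirmatory baseline biopsy at N_0 = 0
  (negative by definition) may serve as the negative member of a pair.

Per-subject kernel masses are normalized by their cohort average, giving
weights with mean one; TPR/TNR estimates are then weighted frequencies of
the rule's decisions and automatically fall in [0, 1].

The weighted-benefits value of a stabilized rule d averages
TPR(d; t_j, tau) + xi(t_j) TNR(d; t_j, tau) over the landmark grid, where
xi trades false negatives against unnecessary biopsies. Under the
cost-benefit choice xi(s) = {1 - rho(s; tau)} / {rho(s; tau) r}, with
rho(s; tau) = P(s < T <= s + tau | T > s) and r the number of unnecessary
biopsies one accepts to catch one progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import NoSupportError
from .kernels import BandwidthSpec, kernel_1d, kernel_2d, warn_if_boundary
from .simulate import Cohort

__all__ = [
    "PerformanceEstimate",
    "TradeoffSpec",
    "always_biopsy",
    "never_biopsy",
    "decisions_at",
    "tnr_weights",
    "tpr_weights",
    "estimate_tnr",
    "estimate_tpr",
    "estimate_rho",
    "xi_from_rho",
    "resolve_xi",
    "estimate_value",
]

# A decision rule maps (covariate vector z, landmark time s) -> {+1, -1};
# +1 means "biopsy at s + tau". Ties in linear rules resolve to +1
# (conservative: when in doubt, biopsy).
DecisionRule = Callable[[np.ndarray, float], int]


def always_biopsy(z, s) -> int:
    return 1


def never_biopsy(z, s) -> int:
    return -1


@dataclass(frozen=True)
class PerformanceEstimate:
    """TPR/TNR of a rule at one landmark, with effective data masses."""

    s: float
    tau: float
    tpr: float
    tnr: float
    n_eff_pos: float  # count of subjects with kernel mass on a neg-pos pair
    n_eff_neg: float  # count of eligible subjects with negative-biopsy mass


@dataclass(frozen=True)
class TradeoffSpec:
    """How the TPR/TNR trade-off weight xi(s) is chosen.

    mode "fixed_xi": xi_values is a scalar, a sequence aligned with the
    landmark grid, or a mapping landmark -> xi. mode "cost_benefit":
    xi(s) is estimated as {1 - rho_hat(s)} / {rho_hat(s) r}.
    """

    mode: str = "fixed_xi"
    xi_values: float | Sequence[float] | Mapping[float, float] | None = 1.0
    r: float | None = None

    def __post_init__(self):
        if self.mode not in ("fixed_xi", "cost_benefit"):
            raise ValueError(f"unknown tradeoff mode {self.mode!r}")
        if self.mode == "cost_benefit" and (self.r is None or self.r <= 0):
            raise ValueError("cost_benefit mode requires r > 0")
        if self.mode == "fixed_xi" and self.xi_values is None:
            raise ValueError("fixed_xi mode requires xi_values")


def decisions_at(cohort: Cohort, rule: DecisionRule, s: float) -> np.ndarray:
    """Evaluate the rule on every subject's covariates at landmark s."""
    out = np.empty(cohort.n, dtype=int)
    for i, subj in enumerate(cohort.subjects):
        d = rule(subj.covariates_at_time(s), s)
        out[i] = 1 if d >= 0 else -1
    return out


def _observed_time_range(cohort: Cohort) -> tuple[float, float]:
    times = [t for subj in cohort.subjects for t in subj.biopsy_times]
    if not times:
        return 0.0, 0.0
    return float(min(times)), float(max(times))


def tnr_weights(cohort: Cohort, t: float, h: float) -> np.ndarray:
    """Per-subject negative-biopsy kernel weights W_{-1,t}.

    For each subject the numerator sums K_h(N_k - t) over that subject's
    observed negative biopsies; it is divided by the average of the same
    quantity over the eligible subset (subjects whose last observed biopsy
    is after t). Ineligible subjects get weight 0; the mean weight over
    the eligible subset is exactly 1.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if h <= 0:
        raise ValueError("h must be positive")
    lo, hi = _observed_time_range(cohort)
    warn_if_boundary(t, h, lo, hi, what="TNR kernel")
    num = np.zeros(cohort.n)
    eligible = np.zeros(cohort.n, dtype=bool)
    for i, subj in enumerate(cohort.subjects):
        eligible[i] = subj.last_time > t
        if len(subj.biopsy_times):
            neg = subj.results == 0
            num[i] = kernel_1d(subj.biopsy_times[neg] - t, h).sum()
    if not eligible.any():
        raise NoSupportError(f"no subject has a biopsy after t={t}")
    denom = num[eligible].mean()
    if denom <= 0:
        raise NoSupportError(
            f"no negative biopsy within [{t - h:.1f}, {t + h:.1f}] among "
            "eligible subjects; widen h or drop this landmark"
        )
    w = np.zeros(cohort.n)
    w[eligible] = num[eligible] / denom
    return w


def tpr_weights(cohort: Cohort, s: float, tau: float, h_tilde: float) -> np.ndarray:
    """Per-subject adjacent negative-positive pair weights W_{1,s}.

    At most one pair per subject contributes (dropout is immediate after
    the first observed positive). The pair mass is
    K~_h(N_k - s - tau, N_(k) - s), normalized by its cohort mean, so the
    returned weights average exactly 1 over the whole cohort.
    """
    if s <= 0 or tau <= 0:
        raise ValueError("s and tau must be positive")
    if h_tilde <= 0:
        raise ValueError("h_tilde must be positive")
    num = np.zeros(cohort.n)
    for i, subj in enumerate(cohort.subjects):
        pair = subj.neg_pos_pair()
        if pair is not None:
            t_neg, t_pos = pair
            num[i] = kernel_2d(t_pos - s - tau, t_neg - s, h_tilde)
    denom = num.mean()
    if denom <= 0:
        raise NoSupportError(
            f"no adjacent negative-positive pair has kernel mass near "
            f"(s={s}, s+tau={s + tau}) with h_tilde={h_tilde:.2f}"
        )
    return num / denom


def estimate_tnr(
    cohort: Cohort, rule: DecisionRule, s: float, tau: float, h: float
) -> float:
    """TNR-hat(d; s, tau): weighted frequency of negative decisions among
    the (kernel-weighted) event-free-past-s+tau population."""
    w = tnr_weights(cohort, s + tau, h)
    # eligible subjects with zero kernel mass still belong to the E_n average
    eligible = np.array(
        [subj.last_time > s + tau for subj in cohort.subjects], dtype=bool
    )
    d = decisions_at(cohort, rule, s)
    return float(np.clip(np.mean((d[eligible] == -1) * w[eligible]), 0.0, 1.0))


def estimate_tpr(
    cohort: Cohort, rule: DecisionRule, s: float, tau: float, h_tilde: float
) -> float:
    """TPR-hat(d; s, tau): weighted frequency of positive decisions among
    the (pair-kernel-weighted) progressing population."""
    w = tpr_weights(cohort, s, tau, h_tilde)
    d = decisions_at(cohort, rule, s)
    return float(np.clip(np.mean((d == 1) * w), 0.0, 1.0))


def estimate_performance(
    cohort: Cohort, rule: DecisionRule, s: float, tau: float, bw: BandwidthSpec
) -> PerformanceEstimate:
    """Joint TPR/TNR estimate at one landmark."""
    w_pos = tpr_weights(cohort, s, tau, bw.h_tilde)
    w_neg = tnr_weights(cohort, s + tau, bw.h)
    d = decisions_at(cohort, rule, s)
    eligible = np.array(
        [subj.last_time > s + tau for subj in cohort.subjects], dtype=bool
    )
    tpr = float(np.clip(np.mean((d == 1) * w_pos), 0.0, 1.0))
    tnr = float(np.clip(np.mean((d[eligible] == -1) * w_neg[eligible]), 0.0, 1.0))
    return PerformanceEstimate(
        s=s,
        tau=tau,
        tpr=tpr,
        tnr=tnr,
        n_eff_pos=float((w_pos > 0).sum()),
        n_eff_neg=float((w_neg > 0).sum()),
    )


_RHO_EPS = 1e-6


def estimate_rho(cohort: Cohort, s: float, tau: float, h_tilde: float) -> float:
    """Conditional progression probability rho(s; tau) = P(s < T <= s+tau | T > s).

    Estimated from adjacent observed biopsy pairs near (s, s + tau): the
    kernel-smoothed mass of negative-positive pairs (events inside the
    window) against negative-negative pairs (still event-free at the
    second biopsy), rho_hat = p1 / (p1 + p2), clipped away from {0, 1}.
    """
    if s <= 0 or tau <= 0:
        raise ValueError("s and tau must be positive")
    p1 = 0.0  # neg-pos mass
    p2 = 0.0  # neg-neg mass
    for subj in cohort.subjects:
        for t0, t1, r0, r1 in subj.adjacent_pairs():
            if r0 != 0:
                continue
            mass = kernel_2d(t1 - s - tau, t0 - s, h_tilde)
            if r1 == 1:
                p1 += mass
            else:
                p2 += mass
    if p1 + p2 <= 0:
        raise NoSupportError(
            f"no adjacent biopsy pair has kernel mass near (s={s}, s+tau={s + tau})"
        )
    return float(np.clip(p1 / (p1 + p2), _RHO_EPS, 1.0 - _RHO_EPS))


def xi_from_rho(rho: float, r: float) -> float:
    """Cost-benefit trade-off weight xi = (1 - rho) / (rho r)."""
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    return (1.0 - rho) / (rho * r)


def resolve_xi(
    cohort: Cohort,
    tradeoff: TradeoffSpec,
    landmarks: Sequence[float],
    tau: float,
    bw: BandwidthSpec,
) -> dict[float, float]:
    """Per-landmark xi values; estimates rho from the cohort in
    cost-benefit mode. Landmarks without pair support are dropped with a
    warning."""
    out: dict[float, float] = {}
    if tradeoff.mode == "fixed_xi":
        xv = tradeoff.xi_values
        for j, t in enumerate(landmarks):
            if isinstance(xv, Mapping):
                out[t] = float(xv[t])
            elif np.isscalar(xv):
                out[t] = float(xv)
            else:
                out[t] = float(xv[j])
    else:
        for t in landmarks:
            try:
                rho = estimate_rho(cohort, t, tau, bw.h_tilde)
            except NoSupportError as err:
                warnings.warn(f"dropping landmark {t}: {err}", stacklevel=2)
                continue
            out[t] = xi_from_rho(rho, tradeoff.r)
    if any(v <= 0 for v in out.values()):
        raise ValueError("xi values must be positive")
    return out


def estimate_value(
    cohort: Cohort,
    rule: DecisionRule,
    landmarks: Sequence[float],
    tradeoff: TradeoffSpec,
    tau: float,
    bw: BandwidthSpec,
) -> float:
    """Weighted-benefits value of a stabilized rule:
    J^{-1} sum_j [TPR-hat(t_j) + xi(t_j) TNR-hat(t_j)].

    Landmarks without kernel support are dropped with a warning and J
    reduced; if none survive, NoSupportError propagates.
    """
    xi = resolve_xi(cohort, tradeoff, landmarks, tau, bw)
    terms = []
    for t in landmarks:
        if t not in xi:
            continue
        try:
            tpr = estimate_tpr(cohort, rule, t, tau, bw.h_tilde)
            tnr = estimate_tnr(cohort, rule, t, tau, bw.h)
        except NoSupportError as err:
            warnings.warn(f"dropping landmark {t}: {err}", stacklevel=2)
            continue
        terms.append(tpr + xi[t] * tnr)
    if not terms:
        raise NoSupportError("no landmark has kernel support")
    return float(np.mean(terms))
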