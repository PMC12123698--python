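"""Reduced-fidelity comparators: IPCW and current-status TPR/TNR.

Both baselines ignore part of the observation structure and are the
reference points for the bias study:

* IPCW treats the time of the first observed *positive biopsy* as a
  right-censored event time T* (censored at the last observed biopsy when
  no positive occurs) and reweights by the Kaplan-Meier estimate of the
  censoring distribution. Because T* lags the true progression time T by
  up to a full biopsy interval, events near the landmark window are
  misplaced and the estimates are biased, increasingly so for sparse
  biopsy schedules.

* The current-status (KR-CS) estimator kernel-smooths the biopsy status
  indicator at s and s + tau using *all* observed biopsies, as if subjects
  kept being examined after progression. Under progression-triggered
  dropout the positive statuses after the first are unobservable, which
  biases the smoothed survival contrast.

A policy-learning comparator ("IPCW-weighted OSF") plugs IPCW-derived case
and control weights into the same surrogate-loss program used by OSF-I,
isolating the effect of the weighting scheme on the learned rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from .exceptions import NoSupportError
from .estimators import DecisionRule, PerformanceEstimate, decisions_at, xi_from_rho
from .kernels import kernel_1d
from .policy import WeightedSample
from .simulate import Cohort

__all__ = [
    "KMCensoringEstimate",
    "surrogate_event_times",
    "fit_censoring_km",
    "ipcw_tpr_tnr",
    "ipcw_rho",
    "kr_cs_tpr",
    "build_ipcw_weighted_sample",
]

_G_FLOOR = 0.05  # weight cap 1/_G_FLOOR when KM support runs out


@dataclass
class KMCensoringEstimate:
    """Kaplan-Meier fit of the censoring survival G(t) = P(C > t)."""

    kmf: KaplanMeierFitter

    def survival(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        # left limit G(t-): weights for events use the at-risk probability
        g = self.kmf.survival_function_at_times(times - 1e-9).to_numpy()
        if (g < _G_FLOOR).any():
            warnings.warn(
                "censoring KM support exhausted; IPCW weights capped at "
                f"{1 / _G_FLOOR:.0f}",
                stacklevel=2,
            )
        return np.maximum(g, _G_FLOOR)


def surrogate_event_times(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Right-censored surrogate (T*, event): first observed positive biopsy
    time, censored at the last observed biopsy otherwise."""
    U = np.zeros(cohort.n)
    event = np.zeros(cohort.n, dtype=bool)
    for i, subj in enumerate(cohort.subjects):
        if len(subj.biopsy_times) == 0:
            continue
        pos = np.flatnonzero(subj.results == 1)
        if len(pos):
            U[i] = subj.biopsy_times[pos[0]]
            event[i] = True
        else:
            U[i] = subj.biopsy_times[-1]
    return U, event


def fit_censoring_km(cohort: Cohort) -> KMCensoringEstimate:
    U, event = surrogate_event_times(cohort)
    kmf = KaplanMeierFitter()
    kmf.fit(U, event_observed=~event)
    return KMCensoringEstimate(kmf=kmf)


def ipcw_tpr_tnr(
    cohort: Cohort, rule: DecisionRule, s: float, tau: float
) -> PerformanceEstimate:
    """IPCW TPR/TNR of a rule at landmark s, treating the first-positive-
    biopsy time as a right-censored event time.

    Cases are subjects with an event in (s, s + tau], weighted by
    1/G-hat(T*-); controls are subjects under observation past s + tau
    (their common weight 1/G-hat(s + tau) cancels).
    """
    U, event = surrogate_event_times(cohort)
    km = fit_censoring_km(cohort)
    d = decisions_at(cohort, rule, s)
    cases = event & (U > s) & (U <= s + tau)
    controls = U > s + tau
    if not cases.any() or not controls.any():
        raise NoSupportError(
            f"no IPCW cases or controls in window (s={s}, s+tau={s + tau})"
        )
    w_case = 1.0 / km.survival(U[cases])
    tpr = float((w_case * (d[cases] == 1)).sum() / w_case.sum())
    tnr = float((d[controls] == -1).mean())
    return PerformanceEstimate(
        s=s,
        tau=tau,
        tpr=tpr,
        tnr=tnr,
        n_eff_pos=float(cases.sum()),
        n_eff_neg=float(controls.sum()),
    )


def ipcw_rho(cohort: Cohort, s: float, tau: float) -> float:
    """IPCW estimate of rho(s; tau) from the surrogate event time."""
    U, event = surrogate_event_times(cohort)
    km = fit_censoring_km(cohort)
    cases = event & (U > s) & (U <= s + tau)
    controls = U > s + tau
    if not cases.any() and not controls.any():
        raise NoSupportError(f"no subject at risk past s={s}")
    num = (1.0 / km.survival(U[cases])).sum() if cases.any() else 0.0
    den = num + (controls.sum() / max(km.survival(np.array([s + tau]))[0], _G_FLOOR))
    if den <= 0:
        raise NoSupportError(f"no IPCW risk mass at s={s}")
    return float(np.clip(num / den, 1e-6, 1 - 1e-6))


def _status_smooth(cohort: Cohort, d: np.ndarray, t: float, h: float):
    """Kernel-smoothed mass of negative statuses at time t, split by
    decision arm, over all observed biopsies (current-status device)."""
    num_by_arm = {1: 0.0, -1: 0.0}
    total = 0.0
    for i, subj in enumerate(cohort.subjects):
        if not len(subj.biopsy_times):
            continue
        k = kernel_1d(subj.biopsy_times - t, h)
        total += k.sum()
        num_by_arm[int(d[i])] += (k * (subj.results == 0)).sum()
    return num_by_arm, total


def kr_cs_tpr(
    cohort: Cohort, rule: DecisionRule, s: float, tau: float, h: float
) -> float:
    """Current-status TPR estimate ignoring progression-triggered dropout.

    Smooths P{d = a, T > t} at t = s and s + tau from the biopsy status
    indicators and forms
    TPR = [S_1(s) - S_1(s+tau)] / [S(s) - S(s+tau)], clipped to [0, 1].
    """
    d = decisions_at(cohort, rule, s)
    num_s, tot_s = _status_smooth(cohort, d, s, h)
    num_st, tot_st = _status_smooth(cohort, d, s + tau, h)
    if tot_s <= 0 or tot_st <= 0:
        raise NoSupportError(f"no biopsy mass near s={s} or s+tau={s + tau}")
    S1_s, Sm1_s = num_s[1] / tot_s, num_s[-1] / tot_s
    S1_st, Sm1_st = num_st[1] / tot_st, num_st[-1] / tot_st
    denom = (S1_s + Sm1_s) - (S1_st + Sm1_st)
    if denom <= 0:
        raise NoSupportError(
            f"current-status survival contrast non-positive at s={s}"
        )
    return float(np.clip((S1_s - S1_st) / denom, 0.0, 1.0))


def build_ipcw_weighted_sample(
    cohort: Cohort,
    landmarks: Sequence[float],
    r: float,
    tau: float,
) -> WeightedSample:
    """IPCW analogue of the OSF-I weighted sample.

    Per (subject, landmark): a case (event in (s, s+tau]) carries label +1
    with its inverse-censoring weight; a control (under observation past
    s+tau) carries label -1 with weight xi(s). Both weight families are
    normalized to cohort-mean one, mirroring the kernel-weight scale, and
    xi(s) comes from the IPCW estimate of rho(s; tau).
    """
    U, event = surrogate_event_times(cohort)
    km = fit_censoring_km(cohort)
    X_rows, y_rows, w_rows, lm_rows, subj_rows = [], [], [], [], []
    kept = 0
    for t in landmarks:
        try:
            xi = xi_from_rho(ipcw_rho(cohort, t, tau), r)
        except NoSupportError as err:
            warnings.warn(f"dropping landmark {t}: {err}", stacklevel=2)
            continue
        cases = event & (U > t) & (U <= t + tau)
        controls = U > t + tau
        if not cases.any() and not controls.any():
            continue
        kept += 1
        # cohort-mean-one normalization, mirroring the kernel weights
        w_case = np.zeros(cohort.n)
        w_ctrl = np.zeros(cohort.n)
        if cases.any():
            w_case[cases] = 1.0 / km.survival(U[cases])
            w_case /= w_case.mean()
        if controls.any():
            w_ctrl[controls] = 1.0
            w_ctrl /= w_ctrl.mean()
        signed = w_case - xi * w_ctrl
        for i in np.flatnonzero(signed != 0.0):
            X_rows.append(cohort.subjects[i].covariates_at_time(t))
            y_rows.append(1 if signed[i] > 0 else -1)
            w_rows.append(abs(signed[i]))
            lm_rows.append(t)
            subj_rows.append(i)
    if not y_rows:
        raise NoSupportError("no (subject, landmark) row has nonzero IPCW weight")
    p = len(X_rows[0])
    return WeightedSample(
        X=np.vstack(X_rows),
        y=np.asarray(y_rows, dtype=int),
        w=np.asarray(w_rows, dtype=float),
        landmark=np.asarray(lm_rows, dtype=float),
        subject=np.asarray(subj_rows, dtype=int),
        n_subjects=cohort.n,
        n_landmarks=kept,
        feature_names=[f"z{l + 1}" for l in range(p)],
    )
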