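"""OSF-I: surrogate-loss learning of the tailored surveillance rule.

Maximizing the estimated weighted-benefits value of a stabilized linear
rule is a weighted 0-1 classification problem over stacked
(subject, landmark) rows. With the logistic surrogate phi and a linear
decision function f(z) = b0 + z^T b, the program

    min_f  J^{-1} sum_j E_n[ W_+ phi{f(Z)} + W_- phi{-f(Z)} ] + lambda ||b||^2

is a weighted ridge-penalized logistic regression, where
W_+ = (W_1 - xi W_{-1})_+ and W_- = (W_1 - xi W_{-1})_- are the positive
and negative parts of the signed kernel-weight difference at each
landmark. Equivalently each row carries label sign(W_1 - xi W_{-1}) and
weight |W_1 - xi W_{-1}|; the two formulations have identical objectives.
The fitted rule is d(z) = sgn{f(z)}, with sgn(0) = +1 (ties go to biopsy).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .exceptions import NoSupportError, OptimizationError
from .kernels import BandwidthSpec
from .simulate import Cohort, subcohort
from .estimators import (
    TradeoffSpec,
    estimate_value,
    resolve_xi,
    tnr_weights,
    tpr_weights,
)

__all__ = [
    "WeightedSample",
    "LinearRule",
    "build_weighted_sample",
    "penalized_objective",
    "fit_osf_i",
    "cross_validate",
]


@dataclass
class WeightedSample:
    """Stacked (subject, landmark) rows for the weighted classification.

    Labels are sign(W_1 - xi W_{-1}) and weights its absolute value; rows
    with zero signed weight are dropped. Weights are rescaled within each
    landmark so that their subject-average is one, which makes the ridge
    penalty comparable across sample sizes and bandwidths.
    """

    X: np.ndarray  # (m, p) covariates at the row's landmark
    y: np.ndarray  # (m,) labels in {+1, -1}
    w: np.ndarray  # (m,) positive weights
    landmark: np.ndarray  # (m,) landmark time of each row
    subject: np.ndarray  # (m,) subject index of each row
    n_subjects: int
    n_landmarks: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class LinearRule:
    """Stabilized linear decision rule d(z) = sgn(intercept + z^T coef)."""

    coefficients: np.ndarray
    intercept: float
    lam: float | None = None
    C_b: float | None = None
    feature_names: tuple[str, ...] = ()

    def decision_function(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.intercept + z @ self.coefficients

    def __call__(self, z, s: float | None = None) -> int:
        return 1 if self.decision_function(z) >= 0 else -1

    def decide(self, Z: np.ndarray) -> np.ndarray:
        """Vectorized decisions over rows of Z; ties map to +1."""
        f = self.decision_function(np.atleast_2d(Z))
        return np.where(f >= 0, 1, -1)

    def to_json(self, **extra) -> str:
        payload = {
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "lambda": self.lam,
            "C_b": self.C_b,
            "feature_names": list(self.feature_names),
        }
        payload.update(extra)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearRule":
        d = json.loads(text)
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            lam=d.get("lambda"),
            C_b=d.get("C_b"),
            feature_names=tuple(d.get("feature_names", ())),
        )


def build_weighted_sample(
    cohort: Cohort,
    landmarks: Sequence[float],
    tradeoff: TradeoffSpec,
    tau: float,
    bw: BandwidthSpec,
) -> WeightedSample:
    """Assemble the weighted classification sample from kernel weights.

    For each landmark t_j with kernel support, each subject contributes the
    signed weight W_{1,t_j} - xi(t_j) W_{-1,t_j+tau}; rows where it is
    exactly zero are dropped. Landmarks where either weight family has no
    support are dropped with a warning.
    """
    xi = resolve_xi(cohort, tradeoff, landmarks, tau, bw)
    X_rows, y_rows, w_rows, lm_rows, subj_rows = [], [], [], [], []
    kept_landmarks = 0
    for t in landmarks:
        if t not in xi:
            continue
        try:
            w1 = tpr_weights(cohort, t, tau, bw.h_tilde)
            wm1 = tnr_weights(cohort, t + tau, bw.h)
        except NoSupportError as err:
            warnings.warn(f"dropping landmark {t}: {err}", stacklevel=2)
            continue
        signed = w1 - xi[t] * wm1
        nz = signed != 0.0
        if not nz.any():
            continue
        kept_landmarks += 1
        absw = np.abs(signed[nz])
        # mean-one weight normalization within the landmark (subject average)
        absw = absw / (absw.sum() / cohort.n)
        for i, wi in zip(np.flatnonzero(nz), absw):
            X_rows.append(cohort.subjects[i].covariates_at_time(t))
            y_rows.append(1 if signed[i] > 0 else -1)
            w_rows.append(wi)
            lm_rows.append(t)
            subj_rows.append(i)
    if not y_rows:
        raise NoSupportError("no (subject, landmark) row has nonzero weight")
    p = len(X_rows[0])
    return WeightedSample(
        X=np.vstack(X_rows),
        y=np.asarray(y_rows, dtype=int),
        w=np.asarray(w_rows, dtype=float),
        landmark=np.asarray(lm_rows, dtype=float),
        subject=np.asarray(subj_rows, dtype=int),
        n_subjects=cohort.n,
        n_landmarks=kept_landmarks,
        feature_names=[f"z{l + 1}" for l in range(p)],
    )


def penalized_objective(
    sample: WeightedSample, coef: np.ndarray, intercept: float, lam: float
) -> float:
    """The surrogate objective J^{-1} E_n[w * log(1 + e^{-y f})] + lam ||coef||^2.

    The empirical average is over subjects within each landmark (divide by
    n_subjects), then averaged over landmarks; the intercept is not
    penalized.
    """
    f = intercept + sample.X @ coef
    loss = np.logaddexp(0.0, -sample.y * f)
    scale = sample.n_landmarks * sample.n_subjects
    return float((sample.w * loss).sum() / scale + lam * coef @ coef)


def _objective_and_grad(theta, sample: WeightedSample, lam: float):
    intercept, coef = theta[0], theta[1:]
    f = intercept + sample.X @ coef
    yf = sample.y * f
    loss = np.logaddexp(0.0, -yf)
    scale = sample.n_landmarks * sample.n_subjects
    val = (sample.w * loss).sum() / scale + lam * coef @ coef
    # d/df log(1+e^{-yf}) = -y sigma(-yf)
    g_f = -sample.y * expit(-yf) * sample.w / scale
    grad = np.empty_like(theta)
    grad[0] = g_f.sum()
    grad[1:] = sample.X.T @ g_f + 2.0 * lam * coef
    return val, grad


def fit_osf_i(
    sample: WeightedSample,
    lam: float,
    C_b: float | None = None,
    max_iter: int = 500,
) -> LinearRule:
    """Fit the linear rule by minimizing the ridge-penalized logistic
    surrogate (convex; unique optimum for lam > 0)."""
    if sample.m == 0:
        raise NoSupportError("empty weighted sample")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    theta0 = np.zeros(sample.X.shape[1] + 1)
    res = minimize(
        _objective_and_grad,
        theta0,
        args=(sample, lam),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": max_iter, "gtol": 1e-9, "ftol": 1e-12},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise OptimizationError(
            f"surrogate minimization failed: {res.message}",
            diagnostics={"nit": res.nit, "fun": float(res.fun)},
        )
    return LinearRule(
        coefficients=res.x[1:],
        intercept=float(res.x[0]),
        lam=lam,
        C_b=C_b,
        feature_names=tuple(sample.feature_names),
    )


def _subject_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def cross_validate(
    cohort: Cohort,
    lambda_grid: Sequence[float],
    Cb_grid: Sequence[float],
    landmarks: Sequence[float],
    tradeoff: TradeoffSpec,
    tau: float,
    folds: int = 5,
    seed: int = 0,
) -> tuple[LinearRule, pd.DataFrame]:
    """Select (lambda, C_b) by subject-level K-fold cross-validation.

    For each configuration the rule is fitted on the training folds and
    scored by the estimated weighted-benefits value on the held-out fold
    (weights recomputed on held-out data, with the trade-off resolved on
    the training folds). The configuration maximizing the mean held-out
    value wins (ties break toward the first grid entry); the rule is then
    refitted on the full cohort. Deterministic given the seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not len(lambda_grid) or not len(Cb_grid):
        raise ValueError("grids must be nonempty")
    fold_idx = _subject_folds(cohort.n, folds, seed)
    records = []
    for lam in lambda_grid:
        for C_b in Cb_grid:
            scores = []
            for k, test_idx in enumerate(fold_idx):
                train_idx = np.setdiff1d(np.arange(cohort.n), test_idx)
                train = subcohort(cohort, train_idx)
                test = subcohort(cohort, test_idx)
                try:
                    bw_train = BandwidthSpec(C_b, train.n)
                    sample = build_weighted_sample(
                        train, landmarks, tradeoff, tau, bw_train
                    )
                    rule = fit_osf_i(sample, lam, C_b=C_b)
                    xi_train = resolve_xi(train, tradeoff, landmarks, tau, bw_train)
                    held_out = estimate_value(
                        test,
                        rule,
                        sorted(xi_train),
                        TradeoffSpec(mode="fixed_xi", xi_values=xi_train),
                        tau,
                        BandwidthSpec(C_b, test.n),
                    )
                except NoSupportError as err:
                    warnings.warn(f"fold {k} skipped for (lambda={lam}, "
                                  f"C_b={C_b}): {err}", stacklevel=2)
                    continue
                scores.append(held_out)
            if not scores:
                raise NoSupportError(
                    f"all folds unsupported for (lambda={lam}, C_b={C_b})"
                )
            records.append(
                {
                    "lambda": lam,
                    "C_b": C_b,
                    "mean_value": float(np.mean(scores)),
                    "n_folds": len(scores),
                }
            )
    table = pd.DataFrame.from_records(records)
    best = table.loc[table["mean_value"].idxmax()]
    bw = BandwidthSpec(float(best["C_b"]), cohort.n)
    sample = build_weighted_sample(cohort, landmarks, tradeoff, tau, bw)
    rule = fit_osf_i(sample, float(best["lambda"]), C_b=float(best["C_b"]))
    return rule, table
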