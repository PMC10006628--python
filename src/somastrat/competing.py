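"""Competing-risk estimation: Aalen-Johansen CIF and Fine-Gray regression.

The event of interest (cause 1, hospitalization for heart failure) competes
with all-cause death (cause 2); cause 0 is right censoring.  The cumulative
incidence function (CIF) is estimated nonparametrically by the
Aalen-Johansen product-limit formula, and covariate effects on the
subdistribution hazard are estimated by the Fine-Gray model: subjects who
fail from the competing cause remain in the risk set after their event with
an inverse-probability-of-censoring weight

    w_i(t) = G(t-) / G(min(T_i, t)-),

where G is the Kaplan-Meier estimator of the censoring distribution.  The
weighted partial likelihood is maximized by Newton-Raphson with Breslow tie
handling and step-halving; standard errors come from the inverse observed
information.  The exponentiated coefficient is the subdistribution hazard
ratio (SHR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datatypes import OutcomeData

__all__ = [
    "CifCurve",
    "FineGrayFit",
    "FineGrayEstimator",
    "StepFunction",
    "censoring_survivor",
    "cif_aalen_johansen",
    "fit_fine_gray",
    "wald_test",
]


# ---------------------------------------------------------------------------
# step functions and Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class StepFunction:
    """Right-continuous step function with a left-limit evaluator.

    ``f(t)`` returns the value of the last step at or before ``t``;
    ``f.left(t)`` returns the left limit ``f(t-)``.
    """

    x: np.ndarray  # step locations, sorted ascending
    y: np.ndarray  # value on [x[k], x[k+1])
    y0: float = 1.0  # value before the first step

    def __call__(self, t):
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="right") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.y0)
        return out if np.ndim(t) else float(out)

    def left(self, t):
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="left") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.y0)
        return out if np.ndim(t) else float(out)


def _km(time: np.ndarray, event: np.ndarray) -> StepFunction:
    """Kaplan-Meier survivor of the distribution whose events are *event*."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t)
    n = len(t)
    surv = []
    s = 1.0
    at_risk = n
    for u in uniq:
        here = t == u
        d = int(e[here].sum())
        if d:
            s *= 1.0 - d / at_risk
        at_risk -= int(here.sum())
        surv.append(s)
    return StepFunction(uniq, np.asarray(surv))


def censoring_survivor(outcomes: OutcomeData) -> StepFunction:
    """Kaplan-Meier estimate G of the censoring distribution.

    Censorings are treated as the events and true events as censorings.
    Evaluate with ``G.left(t)`` for the left-continuous version used in the
    subdistribution weights.
    """
    time = np.asarray(outcomes.time, dtype=float)
    cause = np.asarray(outcomes.cause, dtype=int)
    return _km(time, cause == 0)


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence
# ---------------------------------------------------------------------------

@dataclass
class CifCurve:
    """Nonparametric cumulative incidence curves on the event-time grid.

    ``cif[k]`` holds F_k evaluated at each grid time for cause ``k``;
    ``n_at_risk`` is the risk-set size just before each grid time.
    """

    times: np.ndarray
    cif: dict = field(default_factory=dict)
    n_at_risk: np.ndarray = None
    survival: np.ndarray = None

    def values_for(self, cause: int) -> np.ndarray:
        return self.cif[cause]

    def at(self, t: float, cause: int) -> float:
        """CIF of *cause* evaluated at time *t* (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[cause][idx])

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.times, "n_at_risk": self.n_at_risk, "survival": self.survival}
        for k, v in self.cif.items():
            d[f"cif_{k}"] = v
        return pd.DataFrame(d)


def cif_aalen_johansen(outcomes: OutcomeData, cause: int = 1) -> CifCurve:
    """Aalen-Johansen estimate of the cumulative incidence of *cause*.

    F_k(t) = sum_{t_j <= t} S(t_j-) d_kj / n_j with S the all-cause
    Kaplan-Meier survivor.  Curves for every observed cause are computed on
    the same grid; *cause* only controls the warning for an empty cause.
    """
    time = np.asarray(outcomes.time, dtype=float)
    c = np.asarray(outcomes.cause, dtype=int)
    if len(time) == 0:
        raise ValueError("need at least one subject")
    causes = sorted(k for k in np.unique(c) if k != 0)
    if cause not in causes:
        warnings.warn(f"no events of cause {cause}; returning flat zero curve")
        causes = sorted(set(causes) | {cause})
    uniq = np.unique(time)
    n = len(time)
    s_prev = 1.0
    at_risk = n
    surv, nrisk = [], []
    inc = {k: [] for k in causes}
    cum = {k: 0.0 for k in causes}
    for u in uniq:
        here = time == u
        d_all = int((here & (c != 0)).sum())
        nrisk.append(at_risk)
        for k in causes:
            d_k = int((here & (c == k)).sum())
            cum[k] += s_prev * d_k / at_risk
            inc[k].append(cum[k])
        if d_all:
            s_prev *= 1.0 - d_all / at_risk
        at_risk -= int(here.sum())
        surv.append(s_prev)
    return CifCurve(
        times=uniq,
        cif={k: np.asarray(v) for k, v in inc.items()},
        n_at_risk=np.asarray(nrisk),
        survival=np.asarray(surv),
    )


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution hazard regression
# ---------------------------------------------------------------------------

@dataclass
class FineGrayFit:
    """Result of a Fine-Gray fit: coefficients with Wald inference."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    names: tuple = ()

    @property
    def shr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "shr": self.shr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "z": self.z,
                "p": self.p,
            },
            index=list(self.names) if len(self.names) else None,
        )


def _subdist_design(time: np.ndarray, cause: np.ndarray):
    """Risk-set weights of the subdistribution partial likelihood.

    Returns (event_times, d, case_lists, W) where ``W[j, i]`` is the weight
    of subject i in the risk set at the j-th distinct cause-1 event time.
    """
    G = _km(time, cause == 0)
    ev = np.unique(time[cause == 1])
    J, n = len(ev), len(time)
    W = np.zeros((J, n))
    g_at_ev = G.left(ev)  # G(s-)
    g_at_T = G.left(time)  # G(T_i-)
    for j, s in enumerate(ev):
        still = time >= s
        W[j, still] = 1.0
        late2 = (cause == 2) & (time < s)
        if late2.any():
            W[j, late2] = g_at_ev[j] / g_at_T[late2]
    d = np.array([int(((time == s) & (cause == 1)).sum()) for s in ev])
    cases = [np.flatnonzero((time == s) & (cause == 1)) for s in ev]
    return ev, d, cases, W


def _fg_loglik_score_info(beta, X, d, cases, W, want_derivs=True):
    eta = np.clip(X @ beta, -500, 500)
    w_exp = W * np.exp(eta)[None, :]
    S0 = w_exp.sum(axis=1)
    ll = sum(eta[c].sum() for c in cases) - float(d @ np.log(S0))
    if not want_derivs:
        return ll, None, None
    S1 = w_exp @ X  # J x p
    xbar = S1 / S0[:, None]
    U = np.zeros_like(beta)
    for j, c in enumerate(cases):
        U += X[c].sum(axis=0) - d[j] * xbar[j]
    p = X.shape[1]
    info = np.zeros((p, p))
    for j in range(p):
        S2j = w_exp @ (X * X[:, [j]])  # J x p, rows = sum w e x_j x
        info[j] += (d[:, None] * (S2j / S0[:, None] - xbar[:, [j]] * xbar)).sum(axis=0)
    return ll, U, info


class FineGrayEstimator(BaseEstimator):
    """Fine-Gray subdistribution-hazard regression, scikit-learn style.

    Parameters
    ----------
    max_iter : int
        Newton-Raphson iteration cap; non-convergence raises.
    tol : float
        Relative log-likelihood change declaring convergence.
    separation_bound : float
        A coefficient magnitude beyond this is treated as (quasi-)complete
        separation and raises.

    Attributes
    ----------
    coef_ : (p,) coefficient vector (log subdistribution hazard ratios)
    se_ : (p,) model-based standard errors
    result_ : FineGrayFit with SHR, confidence intervals and Wald p-values
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-9,
                 separation_bound: float = 20.0):
        self.max_iter = max_iter
        self.tol = tol
        self.separation_bound = separation_bound

    def fit(self, X, y):
        """Fit to covariates *X* and outcomes *y*.

        *y* is an OutcomeData, or an (n, 2) array of (time, cause).
        """
        if isinstance(y, OutcomeData):
            time = np.asarray(y.time, dtype=float)
            cause = np.asarray(y.cause, dtype=int)
        else:
            y = np.asarray(y, dtype=float)
            time, cause = y[:, 0], y[:, 1].astype(int)
        names = tuple(X.columns) if hasattr(X, "columns") else ()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.isfinite(X).all():
            bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
            raise ValueError(f"non-finite covariates for subjects {list(bad[:5])}")
        if X.shape[0] != len(time):
            raise ValueError("X and outcomes have different lengths")
        if (cause == 1).sum() == 0:
            raise ValueError("need at least one cause-1 event")
        const = np.ptp(X, axis=0) == 0
        if const.any():
            raise ValueError(f"constant covariate columns: {list(np.flatnonzero(const))}")

        ev, d, cases, W = _subdist_design(time, cause)
        beta = np.zeros(X.shape[1])
        ll, U, info = _fg_loglik_score_info(beta, X, d, cases, W)
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(info, U)
            except np.linalg.LinAlgError as exc:
                raise ValueError("singular information matrix") from exc
            # step-halving keeps the ascent monotone
            factor = 1.0
            for _ in range(30):
                cand = beta + factor * step
                ll_new, _, _ = _fg_loglik_score_info(cand, X, d, cases, W, False)
                if ll_new >= ll - 1e-12:
                    break
                factor /= 2.0
            else:
                raise ValueError(
                    f"no ascent step found at iteration {n_iter}; beta={beta}"
                )
            beta = cand
            if np.abs(beta).max() > self.separation_bound:
                raise ValueError(
                    "coefficient diverged (|beta| > "
                    f"{self.separation_bound}); data likely separated"
                )
            rel = abs(ll_new - ll) / (abs(ll) + 1.0)
            ll, U, info = _fg_loglik_score_info(beta, X, d, cases, W)
            if rel < self.tol:
                converged = True
                break
        if not converged:
            raise ValueError(
                f"Fine-Gray did not converge in {self.max_iter} iterations; "
                f"last beta={beta}, loglik={ll}"
            )
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        self.coef_ = beta
        self.se_ = se
        self.loglik_ = ll
        self.n_iter_ = n_iter
        self.result_ = FineGrayFit(beta, se, ll, n_iter, True, names)
        return self

    def predict(self, X):
        """Linear predictor (log relative subdistribution hazard)."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_


def fit_fine_gray(X, outcomes: OutcomeData, **kwargs) -> FineGrayFit:
    """Functional wrapper over :class:`FineGrayEstimator`."""
    return FineGrayEstimator(**kwargs).fit(X, outcomes).result_


def wald_test(fit: FineGrayFit, index: int = 0) -> float:
    """Two-sided Wald p-value for one coefficient, p = 2(1 - Phi(|b/se|))."""
    se = np.atleast_1d(fit.se)[index]
    if not se > 0:
        raise ValueError("standard error must be positive")
    b = np.atleast_1d(fit.beta)[index]
    return float(2.0 * stats.norm.sf(abs(b / se)))
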