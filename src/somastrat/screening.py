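"""High-dimensional univariate screening of proteins against heart-failure
occurrence with familywise error-rate control.

Each protein gets its own single-covariate Fine-Gray fit; the Wald p-value
is compared with the Bonferroni threshold alpha/m, with m fixed at the
number of proteins entered (fit failures stay in the denominator).  The
per-protein fits share the outcome-derived risk-set weights, so they are
solved simultaneously by a vectorized Newton iteration; the scalar
estimator in :mod:`somastrat.competing` is the reference path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .competing import _subdist_design
from .datatypes import OutcomeData
from .preprocess import ProteinMatrix

__all__ = [
    "ScreenResult",
    "UnivariateFineGrayScreen",
    "bonferroni_threshold",
    "univariate_screen",
    "direction_concordance",
    "correlation_summary",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test level alpha/m controlling FWER at alpha over m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class ScreenResult:
    """Per-protein screening record with the selection threshold."""

    table: pd.DataFrame  # columns: beta, se, shr, p, converged, selected
    alpha: float
    m: int

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m)

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def _batch_univariate_fine_gray(X: np.ndarray, time: np.ndarray,
                                cause: np.ndarray, max_iter: int = 50,
                                tol: float = 1e-10, bound: float = 20.0):
    """Solve p independent single-covariate Fine-Gray fits at once.

    Returns (beta, se, converged) arrays of length p.  The score and
    information of each fit are computed with shared IPCW risk-set weights;
    Newton steps are clipped to +-1 to keep the concave ascent stable
    without per-protein step-halving.
    """
    n, p = X.shape
    ev, d, cases, W = _subdist_design(time, cause)
    case_idx = np.concatenate(cases) if cases else np.array([], dtype=int)
    sum_x_cases = X[case_idx].sum(axis=0)  # (p,)

    beta = np.zeros(p)
    active = np.ones(p, dtype=bool)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        eta = np.clip(X * beta[None, :], -200, 200)
        E = np.exp(eta)
        S0 = W @ E                      # J x p
        S1 = W @ (X * E)
        S2 = W @ (X * X * E)
        xbar = S1 / S0
        U = sum_x_cases - (d[:, None] * xbar).sum(axis=0)
        info = (d[:, None] * (S2 / S0 - xbar ** 2)).sum(axis=0)
        step = np.where(info > 0, U / np.where(info > 0, info, 1.0), 0.0)
        step = np.clip(step, -1.0, 1.0)
        beta = beta + np.where(active, step, 0.0)
        newly_done = np.abs(step) < tol
        active &= ~newly_done
        if not active.any():
            break
    converged = ~active & (np.abs(beta) <= bound) & (info > 0)
    se = np.sqrt(np.where(info > 0, 1.0 / np.where(info > 0, info, np.nan), np.nan))
    beta = np.where(converged, beta, np.nan)
    se = np.where(converged, se, np.nan)
    return beta, se, converged


class UnivariateFineGrayScreen(BaseEstimator):
    """Protein-by-protein Fine-Gray screening with Bonferroni selection.

    Parameters
    ----------
    alpha : float
        FWER level (default 0.05); the per-test threshold is alpha/m.
    backend : {"batch", "loop"}
        "batch" solves all univariate fits with a shared vectorized Newton
        iteration; "loop" calls the scalar estimator per protein (slow,
        used for cross-validation of the batch path).

    Attributes
    ----------
    result_ : ScreenResult
    selected_ : index of proteins with p below the Bonferroni threshold.
    """

    def __init__(self, alpha: float = 0.05, backend: str = "batch"):
        self.alpha = alpha
        self.backend = backend

    def fit(self, X, y):
        if isinstance(X, ProteinMatrix):
            if X.scale != "standardized":
                raise ValueError("screening expects a standardized protein matrix")
            df = X.values
        else:
            df = pd.DataFrame(X)
        if isinstance(y, OutcomeData):
            if not df.index.equals(y.patients):
                if set(df.index) != set(y.patients):
                    raise ValueError("protein matrix and outcomes cover different patients")
                y = y.subset(df.index)
            time = np.asarray(y.time, dtype=float)
            cause = np.asarray(y.cause, dtype=int)
        else:
            arr = np.asarray(y, dtype=float)
            time, cause = arr[:, 0], arr[:, 1].astype(int)

        m = df.shape[1]
        Xv = df.to_numpy(dtype=float)
        if self.backend == "batch":
            beta, se, conv = _batch_univariate_fine_gray(Xv, time, cause)
        elif self.backend == "loop":
            from .competing import FineGrayEstimator
            beta = np.full(m, np.nan)
            se = np.full(m, np.nan)
            conv = np.zeros(m, dtype=bool)
            for j in range(m):
                try:
                    fit = FineGrayEstimator().fit(Xv[:, [j]], np.column_stack([time, cause])).result_
                except ValueError:
                    continue
                beta[j], se[j], conv[j] = fit.beta[0], fit.se[0], True
        else:
            raise ValueError("backend must be 'batch' or 'loop'")

        with np.errstate(invalid="ignore"):
            z = beta / se
            p = 2.0 * stats.norm.sf(np.abs(z))
        thr = bonferroni_threshold(self.alpha, m)
        table = pd.DataFrame(
            {
                "beta": beta,
                "se": se,
                "shr": np.exp(beta),
                "p": p,
                "converged": conv,
                "selected": conv & (p < thr),
            },
            index=df.columns,
        )
        self.result_ = ScreenResult(table=table, alpha=self.alpha, m=m)
        self.selected_ = self.result_.selected
        return self


def univariate_screen(matrix, outcomes, alpha: float = 0.05,
                      backend: str = "batch") -> ScreenResult:
    """One single-covariate Fine-Gray fit per protein; select at alpha/m."""
    return UnivariateFineGrayScreen(alpha=alpha, backend=backend).fit(matrix, outcomes).result_


def direction_concordance(res_deriv: ScreenResult, res_valid: ScreenResult,
                          selected=None):
    """Count same- vs opposite-sign effects in the validation cohort.

    Returns (n_same, n_opposite, opposite_names) over the derivation-
    selected proteins (or an explicit *selected* set).
    """
    if selected is None:
        selected = res_deriv.selected
    selected = pd.Index(selected)
    for res, label in ((res_deriv, "derivation"), (res_valid, "validation")):
        missing = selected.difference(res.table.index)
        if len(missing):
            raise ValueError(f"{label} result missing proteins: {list(missing[:10])}")
    b1 = res_deriv.table.loc[selected, "beta"]
    b2 = res_valid.table.loc[selected, "beta"]
    same = np.sign(b1) == np.sign(b2)
    opposite_names = list(selected[~same])
    return int(same.sum()), int((~same).sum()), opposite_names


def correlation_summary(matrix) -> tuple:
    """Pairwise Pearson correlations of the selected proteins.

    Returns (corr_matrix, (protein_a, protein_b), max_off_diagonal_r).
    """
    df = matrix.values if isinstance(matrix, ProteinMatrix) else pd.DataFrame(matrix)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 proteins for a correlation summary")
    if (df.std(axis=0, ddof=0) == 0).any():
        bad = df.columns[df.std(axis=0, ddof=0) == 0]
        raise ValueError(f"constant columns have undefined correlation: {list(bad)}")
    corr = df.corr()
    c = corr.to_numpy().copy()
    np.fill_diagonal(c, -np.inf)
    i, j = np.unravel_index(np.argmax(c), c.shape)
    return corr, (corr.index[i], corr.columns[j]), float(c[i, j])
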