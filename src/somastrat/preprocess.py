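"""Reagent cleanup, protein aggregation, log2 transform, standardization
and clinical imputation.

The protein matrix goes through a fixed scale progression
``rfu -> log2 -> standardized``; standardization is anchored on the
derivation cohort (its per-protein mean and sample SD, n-1 denominator) and
applied unchanged to any other cohort or single patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import ClinicalTable, SomamerTable

__all__ = [
    "ProteinMatrix",
    "CohortStandardizer",
    "IterativePCAImputer",
    "remove_flagged",
    "aggregate_to_proteins",
    "log2_transform",
    "fit_standardization",
    "apply_standardization",
    "impute_clinical",
]

_SCALES = ("rfu", "log2", "standardized")


@dataclass
class ProteinMatrix:
    """Patients x proteins matrix with an explicit scale tag."""

    values: pd.DataFrame
    scale: str = "rfu"

    def __post_init__(self):
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}")
        if self.values.isna().to_numpy().any():
            raise ValueError("protein matrix must not contain missing values")

    @property
    def proteins(self) -> pd.Index:
        return self.values.columns

    @property
    def patients(self) -> pd.Index:
        return self.values.index

    def _advance(self, new_scale: str) -> None:
        if _SCALES.index(new_scale) != _SCALES.index(self.scale) + 1:
            raise ValueError(f"illegal scale transition {self.scale} -> {new_scale}")


def remove_flagged(table: SomamerTable) -> SomamerTable:
    """Drop SOMAmer columns flagged for removal."""
    flagged = table.somamer_meta.index[table.somamer_meta["flagged_removed"].astype(bool)]
    if len(flagged) == 0:
        return table.copy()
    keep = table.somamer_meta.index.difference(flagged, sort=False)
    if len(keep) == 0 or len(table.analyte_ids().difference(flagged)) == 0:
        raise ValueError("all analyte SOMAmers flagged for removal; nothing left")
    out = SomamerTable(
        table.rfu[keep].copy(),
        table.somamer_meta.loc[keep].copy(),
        table.sample_meta.copy(),
    )
    return out


def aggregate_to_proteins(table: SomamerTable, study_only: bool = True) -> ProteinMatrix:
    """One column per protein symbol, averaging multi-SOMAmer proteins.

    Proteins measured by several SOMAmers get the per-patient arithmetic
    mean of their reagents' RFU; hybridization controls are excluded.  By
    default only study samples are kept (controls are not patients).
    """
    analytes = table.analyte_ids()
    symbols = table.somamer_meta.loc[analytes, "protein_symbol"]
    if (symbols.astype(str).str.strip() == "").any():
        bad = analytes[symbols.astype(str).str.strip() == ""]
        raise ValueError(f"empty protein symbol for somamers {list(bad[:5])}")
    rows = table.samples_of_type("study") if study_only else table.rfu.index
    block = table.rfu.loc[rows, analytes]
    # mean per symbol, preserving first-appearance column order
    grouped = block.T.groupby(symbols, sort=False).mean().T
    order = list(dict.fromkeys(symbols))
    grouped = grouped[order]
    grouped.columns.name = "protein_symbol"
    return ProteinMatrix(grouped, scale="rfu")


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Elementwise log2; requires strictly positive values."""
    matrix._advance("log2")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive value at patient {matrix.values.index[r]!r}, "
            f"protein {matrix.values.columns[c]!r}; cannot take log2"
        )
    return ProteinMatrix(pd.DataFrame(np.log2(vals), index=matrix.values.index,
                                      columns=matrix.values.columns), scale="log2")


class CohortStandardizer(BaseEstimator, TransformerMixin):
    """Derivation-anchored per-protein standardization.

    ``fit`` estimates each protein's mean and sample standard deviation
    (n-1 denominator by default) on the derivation cohort; ``transform``
    maps any cohort — or a single patient — onto
    ``(x - mean) / sd`` using those frozen parameters.

    Attributes
    ----------
    mean_, sd_ : pandas.Series indexed by protein symbol.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        df = X.values if isinstance(X, ProteinMatrix) else pd.DataFrame(X)
        if isinstance(X, ProteinMatrix) and X.scale != "log2":
            raise ValueError("standardization expects a log2-scale matrix")
        if df.shape[0] < 2:
            raise ValueError("need at least 2 patients to estimate an SD")
        self.mean_ = df.mean(axis=0)
        self.sd_ = df.std(axis=0, ddof=self.ddof)
        zero = self.sd_.index[~(self.sd_ > 0)]
        if len(zero):
            raise ValueError(
                f"constant protein columns cannot be standardized: {list(zero[:10])}"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        is_pm = isinstance(X, ProteinMatrix)
        df = X.values if is_pm else pd.DataFrame(X)
        unknown = df.columns.difference(self.mean_.index)
        if len(unknown):
            raise ValueError(f"proteins without standardization parameters: {list(unknown[:10])}")
        z = (df - self.mean_[df.columns]) / self.sd_[df.columns]
        if is_pm:
            X._advance("standardized")
            return ProteinMatrix(z, scale="standardized")
        return z

    def to_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        return pd.DataFrame({"mean": self.mean_, "sd": self.sd_})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ddof: int = 1) -> "CohortStandardizer":
        obj = cls(ddof=ddof)
        obj.mean_ = df["mean"].copy()
        obj.sd_ = df["sd"].copy()
        return obj


def fit_standardization(matrix: ProteinMatrix, ddof: int = 1) -> CohortStandardizer:
    """Estimate per-protein (mean, SD) on the derivation cohort."""
    return CohortStandardizer(ddof=ddof).fit(matrix)


def apply_standardization(matrix: ProteinMatrix, params: CohortStandardizer) -> ProteinMatrix:
    """Project a cohort (or single patient) with frozen derivation parameters."""
    return params.transform(matrix)


class IterativePCAImputer(BaseEstimator, TransformerMixin):
    """Single imputation by iterative truncated principal axes.

    Missing cells start at the column mean; the algorithm then alternates a
    rank-``n_components`` reconstruction (SVD of the column-centered,
    optionally column-scaled matrix) with re-imputation of the missing
    cells until the imputed values change by less than ``tol`` or
    ``max_iter`` iterations.  Observed cells are never altered.

    This is the deterministic single-imputation analogue of iterative PCA
    imputation for mixed clinical tables; binary variables ride along as
    0/1 columns and are not rounded.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-6,
                 max_iter: int = 200, scale: bool = True):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.scale = scale

    def fit_transform(self, X, y=None):
        df = X.values if isinstance(X, ClinicalTable) else pd.DataFrame(X)
        vals = df.to_numpy(dtype=float)
        mask = np.isnan(vals)
        if not mask.any():
            self.converged_ = True
            self.n_iter_ = 0
            return df.copy()
        full_missing = mask.all(axis=0)
        if full_missing.any():
            raise ValueError(
                f"fully missing columns: {list(df.columns[full_missing])}"
            )
        if mask.mean(axis=0).max() >= 0.5:
            warnings.warn("some columns are >=50% missing; imputation may be unstable")

        col_mean = np.nanmean(vals, axis=0)
        col_sd = np.nanstd(vals, axis=0, ddof=0)
        col_sd[col_sd == 0] = 1.0
        scale = col_sd if self.scale else np.ones_like(col_sd)

        M = vals.copy()
        M[mask] = np.take(col_mean, np.nonzero(mask)[1])
        r = min(self.n_components, min(M.shape) - 1) or 1
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            Z = (M - M.mean(axis=0)) / scale
            mu = M.mean(axis=0)
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            recon = (U[:, :r] * s[:r]) @ Vt[:r] * scale + mu
            delta = np.abs(recon[mask] - M[mask])
            M[mask] = recon[mask]
            if delta.size == 0 or delta.max() < self.tol:
                self.converged_ = True
                break
        self.n_iter_ = it
        if not self.converged_:
            warnings.warn(
                f"iterative PCA imputation did not converge in {self.max_iter} iterations"
            )
        out = pd.DataFrame(M, index=df.index, columns=df.columns)
        # observed cells are authoritative
        out = out.where(mask, df)
        return out

    def transform(self, X):
        return self.fit_transform(X)


def impute_clinical(clinical: ClinicalTable, n_components: int = 2,
                    **kwargs) -> ClinicalTable:
    """Complete a clinical table by iterative PCA single imputation."""
    imputer = IterativePCAImputer(n_components=n_components, **kwargs)
    completed = imputer.fit_transform(clinical)
    return ClinicalTable(completed, clinical.binary_vars)
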