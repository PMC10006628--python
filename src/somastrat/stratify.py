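"""Patient stratification: k-means on the selected proteins, silhouette-based
choice of the number of groups, cross-cohort transfer by nearest centroid,
group comparisons and group-level competing-risk models.

Groups are built once on the derivation cohort in the standardized protein
space; validation patients (or a single new patient) are assigned to the
nearest centroid in Euclidean distance.  By convention the group labelled 2
is the one with the higher crude incidence of the event of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .competing import FineGrayFit, fit_fine_gray
from .datatypes import OutcomeData
from .preprocess import ProteinMatrix

__all__ = [
    "ClusterModel",
    "GroupComparison",
    "SilhouetteKMeans",
    "kmeans_fit",
    "average_silhouette",
    "select_k",
    "assign",
    "compare_groups",
    "group_risk_model",
    "sensitivity_drop",
]


def _as_array(matrix):
    if isinstance(matrix, ProteinMatrix):
        return matrix.values.to_numpy(dtype=float), matrix.values.index, matrix.values.columns
    df = pd.DataFrame(matrix)
    return df.to_numpy(dtype=float), df.index, df.columns


def kmeans_fit(matrix, k: int, seed: int = 0, n_restarts: int = 25):
    """Lloyd k-means, best of *n_restarts* greedy k-means++ starts by WCSS."""
    X, _, _ = _as_array(matrix)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of patients ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return km.cluster_centers_, labels


def average_silhouette(matrix, labels) -> float:
    """Overall average silhouette width with Euclidean distance.

    s(i) = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to the
    other members of i's group and b_i the smallest mean distance to
    another group.  Points in singleton groups contribute 0.
    """
    X, _, _ = _as_array(matrix)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 groups")
    D = cdist(X, X)
    n = X.shape[0]
    s = np.zeros(n)
    sizes = {g: int((labels == g).sum()) for g in uniq}
    for g in uniq:
        if sizes[g] == 0:
            raise ValueError(f"group {g} is empty")
    for i in range(n):
        g = labels[i]
        if sizes[g] == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = D[i, labels == g].sum() / (sizes[g] - 1)
        b = min(D[i, labels == h].mean() for h in uniq if h != g)
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


@dataclass
class ClusterModel:
    """Fitted stratification: centroids, labels and the silhouette profile."""

    k: int
    centroids: np.ndarray
    labels: pd.Series              # 1-based group ids, group k = highest risk
    silhouette_by_k: dict
    proteins: tuple = ()
    seed: int = 0
    n_restarts: int = 25

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "proteins": list(self.proteins),
            "silhouette_by_k": {int(k): v for k, v in self.silhouette_by_k.items()},
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "group_sizes": self.labels.value_counts().sort_index().to_dict(),
        }


class SilhouetteKMeans(BaseEstimator, ClusterMixin):
    """k-means with the number of groups chosen by average silhouette width.

    Fits k-means for each k in ``k_range`` (default 2..6, 25 restarts per
    k) and keeps the k maximizing the overall average silhouette width;
    ties break to the smaller k.  ``predict`` assigns new points to the
    nearest centroid (Euclidean), ties to the lowest group index.

    Attributes
    ----------
    k_ : selected number of groups
    cluster_centers_ : (k, p) centroids
    labels_ : 0-based training labels
    silhouette_by_k_ : dict k -> average silhouette width
    """

    def __init__(self, k_range=(2, 3, 4, 5, 6), seed: int = 0, n_restarts: int = 25):
        self.k_range = k_range
        self.seed = seed
        self.n_restarts = n_restarts

    def fit(self, X, y=None):
        Xv, index, cols = _as_array(X)
        if Xv.shape[0] <= max(self.k_range):
            raise ValueError("need more patients than the largest candidate k")
        sil, fits = {}, {}
        for k in self.k_range:
            centroids, labels = kmeans_fit(Xv, k, seed=self.seed,
                                           n_restarts=self.n_restarts)
            sil[k] = average_silhouette(Xv, labels)
            fits[k] = (centroids, labels)
        best = max(sorted(sil), key=lambda k: sil[k])  # ties -> smaller k
        self.k_ = int(best)
        self.cluster_centers_, self.labels_ = fits[best]
        self.silhouette_by_k_ = sil
        self.feature_names_in_ = np.asarray(cols)
        self._index = index
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        Xv, _, _ = _as_array(X)
        if Xv.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError(
                f"dimension mismatch: {Xv.shape[1]} features vs "
                f"{self.cluster_centers_.shape[1]} centroid coordinates"
            )
        D = cdist(Xv, self.cluster_centers_)
        return D.argmin(axis=1)  # argmin takes the lowest index on ties


def select_k(matrix, k_range=(2, 3, 4, 5, 6), seed: int = 0,
             n_restarts: int = 25, outcomes: OutcomeData = None) -> ClusterModel:
    """Fit k-means over *k_range* and keep the silhouette-optimal model.

    When *outcomes* are given, groups are renumbered so that higher group
    ids carry higher crude incidence of the event of interest (group 2 is
    the high-risk group when k=2).
    """
    est = SilhouetteKMeans(k_range=k_range, seed=seed, n_restarts=n_restarts).fit(matrix)
    _, index, cols = _as_array(matrix)
    labels0 = est.labels_
    order = _risk_order(labels0, outcomes, est.k_)
    relabel = {old: new for new, old in enumerate(order)}
    labels = pd.Series([relabel[g] + 1 for g in labels0], index=index, name="group")
    centroids = est.cluster_centers_[order]
    return ClusterModel(
        k=est.k_, centroids=centroids, labels=labels,
        silhouette_by_k=est.silhouette_by_k_, proteins=tuple(cols),
        seed=seed, n_restarts=n_restarts,
    )


def _risk_order(labels0, outcomes, k):
    """Order of raw k-means labels by ascending crude cause-1 incidence."""
    if outcomes is None:
        return list(range(k))
    inc = []
    cause = np.asarray(outcomes.cause, dtype=int)
    for g in range(k):
        m = labels0 == g
        inc.append((cause[m] == 1).mean() if m.any() else 0.0)
    return list(np.argsort(inc, kind="stable"))


def assign(matrix, centroids) -> pd.Series:
    """Nearest-centroid (Euclidean) assignment; 1-based labels.

    Works for a whole cohort or a single patient; exact distance ties go
    to the lowest group index.
    """
    Xv, index, _ = _as_array(matrix)
    centroids = np.asarray(centroids, dtype=float)
    if Xv.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {Xv.shape[1]} proteins, "
            f"centroids have {centroids.shape[1]}"
        )
    D = cdist(Xv, centroids)
    return pd.Series(D.argmin(axis=1) + 1, index=index, name="group")


@dataclass
class GroupComparison:
    """Per-variable two-group tests (Welch t or chi-square)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def compare_groups(data, labels, binary_vars=(), alpha: float = 0.05,
                   continuity: bool = False) -> GroupComparison:
    """Welch's t for continuous and chi-square for categorical variables.

    *data* is a DataFrame (clinical table or protein matrix values);
    *labels* a two-group assignment aligned on the same index.
    """
    if isinstance(data, ProteinMatrix):
        data = data.values
    labels = pd.Series(labels).reindex(data.index)
    groups = np.sort(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {list(groups)}")
    m1, m2 = labels == groups[0], labels == groups[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 members")
    rows = []
    for col in data.columns:
        x = data.loc[m1, col].dropna()
        y = data.loc[m2, col].dropna()
        if col in binary_vars:
            tab = np.array([
                [(x == v).sum() for v in (0, 1)],
                [(y == v).sum() for v in (0, 1)],
            ])
            if (tab.sum(axis=0) == 0).any():
                statv, p = np.nan, 1.0
            else:
                statv, p, _, _ = stats.chi2_contingency(tab, correction=continuity)
            test = "chi2"
        else:
            statv, p = stats.ttest_ind(x, y, equal_var=False)
            test = "welch"
        rows.append((col, test, float(statv), float(p), bool(p < alpha)))
    table = pd.DataFrame(rows, columns=["variable", "test", "statistic", "p",
                                        "significant"]).set_index("variable")
    return GroupComparison(table)


def group_risk_model(labels, outcomes: OutcomeData, adjust=None) -> FineGrayFit:
    """Fine-Gray model of the event of interest on the group indicator.

    *labels* are 1-based group ids (binary); *adjust* is an optional
    DataFrame of covariates (single columns or pairs, already imputed)
    entered alongside the group indicator.
    """
    labels = pd.Series(labels)
    groups = np.sort(labels.unique())
    if len(groups) != 2:
        raise ValueError("group indicator must be binary")
    indicator = (labels == groups[1]).astype(float).rename("group2")
    X = indicator.to_frame()
    if adjust is not None:
        adjust = pd.DataFrame(adjust).reindex(labels.index)
        if adjust.isna().to_numpy().any():
            raise ValueError("adjustment covariates contain missing values; impute first")
        X = pd.concat([X, adjust], axis=1)
    y = outcomes.subset(labels.index)
    return fit_fine_gray(X, y)


def sensitivity_drop(matrix_deriv, drop_proteins, baseline: ClusterModel,
                     matrix_valid=None, seed: int = 0, n_restarts: int = 25,
                     outcomes: OutcomeData = None):
    """Re-cluster without *drop_proteins* and count label changes.

    Re-runs the silhouette-selected k-means on the reduced panel, maps the
    new groups to the baseline groups by maximal label overlap (exhaustive
    over permutations for small k), and counts how many derivation (and
    validation) patients change groups.

    Returns (new_model, n_changed_deriv, n_changed_valid).
    """
    df = matrix_deriv.values if isinstance(matrix_deriv, ProteinMatrix) else pd.DataFrame(matrix_deriv)
    drop = pd.Index(drop_proteins)
    unknown = drop.difference(df.columns)
    if len(unknown):
        raise ValueError(f"drop proteins not in panel: {list(unknown)}")
    keep = df.columns.difference(drop, sort=False)
    if len(keep) == 0:
        raise ValueError("cannot drop every protein in the panel")
    reduced = df[keep]
    model = select_k(reduced, k_range=(baseline.k,), seed=seed,
                     n_restarts=n_restarts, outcomes=outcomes)
    mapping = _best_label_mapping(baseline.labels, model.labels, baseline.k)
    mapped = model.labels.map(mapping)
    model.labels = mapped
    model.centroids = model.centroids[np.argsort([mapping[g + 1] for g in range(model.k)])]
    n_changed = int((mapped != baseline.labels.reindex(mapped.index)).sum())
    n_changed_valid = None
    if matrix_valid is not None:
        dfv = matrix_valid.values if isinstance(matrix_valid, ProteinMatrix) else pd.DataFrame(matrix_valid)
        base_valid = assign(dfv, _baseline_centroids_for(baseline))
        new_valid = assign(dfv[keep], model.centroids)
        n_changed_valid = int((new_valid != base_valid).sum())
    return model, n_changed, n_changed_valid


def _baseline_centroids_for(baseline: ClusterModel):
    return baseline.centroids


def _best_label_mapping(base_labels: pd.Series, new_labels: pd.Series, k: int) -> dict:
    """Bijection new-group -> base-group maximizing the label overlap."""
    from itertools import permutations

    base = base_labels.reindex(new_labels.index)
    best, best_score = None, -1
    for perm in permutations(range(1, k + 1)):
        score = sum(
            int(((new_labels == g) & (base == perm[g - 1])).sum())
            for g in range(1, k + 1)
        )
        if score > best_score:
            best, best_score = perm, score
    return {g: best[g - 1] for g in range(1, k + 1)}
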