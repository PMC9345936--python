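"""Unsupervised phenotype discovery and discriminant-activity ranking.

Patients are clustered on their activity profiles with complete-linkage
agglomerative clustering on Euclidean distances (the dendrogram/heatmap
reading), cut into k clusters with canonical labels A, B, C, ... in
decreasing cluster-size order.  The activities that separate the
phenotypes are then ranked by PLS-DA variable importance in projection
(VIP), computed from a NIPALS PLS2 fit of the one-hot phenotype matrix
on the column-centred activities.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import silhouette_score

__all__ = [
    "PhenotypeAssignment",
    "cluster_patients",
    "silhouette_profile",
    "plsda_vip",
    "top_discriminants",
]


@dataclass
class PhenotypeAssignment:
    """Cluster labels plus the linkage tree that produced them."""

    labels: pd.Series  # subject id -> phenotype letter
    linkage_matrix: np.ndarray  # scipy linkage output (merge heights)
    k: int

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _canonical_letters(raw: np.ndarray, subject_order: list) -> pd.Series:
    """Rename integer clusters to letters by decreasing size.

    Ties in size break by the first subject index appearing in the
    cluster, so the naming is invariant to the arbitrary integer ids
    scipy assigns.
    """
    order = {}
    for cid in np.unique(raw):
        members = np.nonzero(raw == cid)[0]
        order[cid] = (-len(members), members[0])
    ranked = sorted(order, key=order.get)
    letter = {cid: ascii_uppercase[i] for i, cid in enumerate(ranked)}
    return pd.Series([letter[c] for c in raw], index=subject_order, name="phenotype")


def cluster_patients(
    matrix: pd.DataFrame, k: int, scale: str = "zscore"
) -> PhenotypeAssignment:
    """Complete-linkage Euclidean clustering of subjects, cut at k."""
    n = len(matrix)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if matrix.isna().to_numpy().any():
        raise ValueError("activity matrix has missing cells")
    X = matrix.to_numpy(dtype=float)
    if scale == "zscore":
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    elif scale != "none":
        raise ValueError(f"scale must be zscore|none, got {scale!r}")
    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _canonical_letters(raw, list(matrix.index))
    return PhenotypeAssignment(labels=labels, linkage_matrix=Z, k=k)


def silhouette_profile(
    matrix: pd.DataFrame, k_range: range = range(2, 9), scale: str = "zscore"
) -> pd.Series:
    """Average silhouette width for each candidate k (diagnostic only)."""
    out = {}
    for k in k_range:
        if k >= len(matrix):
            break
        assign = cluster_patients(matrix, k, scale=scale)
        X = matrix.to_numpy(dtype=float)
        if scale == "zscore":
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        out[k] = float(silhouette_score(X, assign.labels.to_numpy()))
    return pd.Series(out, name="silhouette")


def plsda_vip(
    matrix: pd.DataFrame, labels: pd.Series, n_components: int = 2
) -> pd.DataFrame:
    """PLS-DA variable importance in projection per activity.

    The one-hot class matrix is regressed on the column-centred activity
    matrix (NIPALS PLS2); for activity j over components a,

        VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

    with SS_a the class variance explained by component a, so that the
    mean squared VIP over the p activities is exactly 1.
    """
    labels = pd.Series(labels).loc[matrix.index]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs >= 2 classes")
    cap = min(len(matrix) - 1, matrix.shape[1])
    if n_components > cap:
        raise ValueError(f"n_components {n_components} exceeds {cap}")
    X = matrix.to_numpy(dtype=float)
    Y = np.stack([(labels == c).to_numpy(float) for c in classes], axis=1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    W = pls.x_weights_  # p x a
    T = pls.x_scores_  # n x a
    Q = pls.y_loadings_  # classes x a
    p = X.shape[1]
    ss = np.einsum("na,na->a", T, T) * np.einsum("ca,ca->a", Q, Q)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip = np.sqrt(p * ((W**2 / wnorm2) @ ss) / ss.sum())
    out = pd.DataFrame(
        {"vip": vip}, index=pd.Index(matrix.columns, name="activity")
    )
    out = out.reset_index().sort_values(
        ["vip", "activity"], ascending=[False, True], kind="stable"
    ).set_index("activity")
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["n_components"] = n_components
    out.attrs["classes"] = classes
    return out


def top_discriminants(vip: pd.DataFrame, n: int) -> list[str]:
    """Top-n activities by descending VIP; ties break alphabetically."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(vip):
        raise ValueError(f"n = {n} exceeds {len(vip)} activities")
    ordered = vip.reset_index().sort_values(
        ["vip", "activity"], ascending=[False, True], kind="stable"
    )
    return list(ordered["activity"].head(n))
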