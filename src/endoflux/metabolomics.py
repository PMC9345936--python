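"""Plasma metabolite table preprocessing and cohort statistics.

The table is a samples x metabolites matrix of strictly positive
concentrations with a per-sample group label (``control`` vs
``patient``, optionally refined by diagnosis).  The processing chain is
the standard one for targeted metabolomics panels: missing-value
imputation (iterative random-forest in the MissForest scheme, or a fast
median fallback), log10 transformation with Pareto scaling, group fold
changes on the raw concentration scale, a volcano analysis (Welch test +
Benjamini-Hochberg FDR, 1.5 fold-change gate) and PCA variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaboliteTable",
    "read_table",
    "impute_missing",
    "normalize",
    "fold_changes",
    "volcano",
    "pca_variance",
]

CONTROL = "control"
PATIENT = "patient"


@dataclass
class MetaboliteTable:
    """Samples x metabolites concentration table with group labels."""

    values: pd.DataFrame  # index: sample ids, columns: metabolite ids
    group: pd.Series  # per-sample: control / patient
    diagnosis: pd.Series | None = None  # optional: IPAH / CTD-aPAH / CTEPH
    missing_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not self.group.index.equals(self.values.index):
            raise ValueError("group labels must cover exactly the samples")
        observed = self.values.to_numpy(dtype=float)
        if np.any(observed[~np.isnan(observed)] <= 0):
            raise ValueError("observed concentrations must be strictly positive")
        if self.missing_fraction > self.missing_threshold:
            raise ValueError(
                f"missing fraction {self.missing_fraction:.3f} exceeds "
                f"threshold {self.missing_threshold}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def subset(self, label: str) -> pd.DataFrame:
        mask = (self.group == label).to_numpy()
        if not mask.any():
            raise ValueError(f"no samples with group label {label!r}")
        return self.values.loc[mask]


def read_table(path: str) -> MetaboliteTable:
    """Read the CSV layout: sample_id, group, then metabolite columns.

    Missing values are empty cells or ``NA``.
    """
    df = pd.read_csv(path, na_values=["NA"], index_col=0)
    if "group" not in df.columns:
        raise ValueError("table CSV must have a 'group' column")
    group = df["group"].astype(str)
    diagnosis = df["diagnosis"].astype(str) if "diagnosis" in df.columns else None
    drop = ["group"] + (["diagnosis"] if diagnosis is not None else [])
    values = df.drop(columns=drop).astype(float)
    return MetaboliteTable(values=values, group=group, diagnosis=diagnosis)


def write_table(table: MetaboliteTable, path: str) -> None:
    df = table.values.copy()
    df.insert(0, "group", table.group)
    if table.diagnosis is not None:
        df.insert(1, "diagnosis", table.diagnosis)
    df.to_csv(path, index_label="sample_id")


# ----------------------------------------------------------------------
# Imputation
# ----------------------------------------------------------------------

def impute_missing(
    table: MetaboliteTable, method: str = "forest", seed: int = 0
) -> MetaboliteTable:
    """Fill missing concentrations; observed values are left untouched.

    ``forest`` runs the MissForest scheme: columns are initialised at
    their medians, then visited (most-missing last) fitting a
    random-forest regressor of the column on all other columns, iterating
    until the mean-squared change of the imputed entries first increases,
    or 10 iterations.  ``median`` is the deterministic per-column-median
    fallback.
    """
    values = table.values
    all_missing = values.columns[values.isna().all()]
    if len(all_missing):
        raise ValueError(f"column(s) entirely missing: {list(all_missing)}")
    few = values.columns[values.notna().sum() < 2]
    if len(few):
        raise ValueError(f"column(s) with <2 observed values: {list(few)}")
    if not values.isna().to_numpy().any():
        return table
    if method == "median":
        filled = values.fillna(values.median())
    elif method == "forest":
        filled = _missforest(values, seed)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return replace(table, values=filled)


def _missforest(values: pd.DataFrame, seed: int, max_iter: int = 10) -> pd.DataFrame:
    X = values.to_numpy(dtype=float).copy()
    nan_mask = np.isnan(X)
    col_order = np.argsort(nan_mask.sum(axis=0))  # least missing first
    medians = np.nanmedian(X, axis=0)
    for j in range(X.shape[1]):
        X[nan_mask[:, j], j] = medians[j]
    prev = X[nan_mask].copy()
    best = X.copy()
    last_change = np.inf
    for it in range(max_iter):
        rng_seed = seed + it  # fresh but reproducible forests each sweep
        for j in col_order:
            miss = nan_mask[:, j]
            if not miss.any():
                continue
            other = np.delete(X, j, axis=1)
            rf = RandomForestRegressor(
                n_estimators=100, random_state=rng_seed + int(j)
            )
            rf.fit(other[~miss], X[~miss, j])
            X[miss, j] = rf.predict(other[miss])
        cur = X[nan_mask]
        change = float(np.mean((cur - prev) ** 2)) if cur.size else 0.0
        if change > last_change:
            X = best  # first increase of the change criterion: stop, keep previous
            break
        best = X.copy()
        last_change = change
        prev = cur.copy()
        if change < 1e-12:
            break
    out = values.copy()
    out.iloc[:, :] = X
    return out


# ----------------------------------------------------------------------
# Normalisation
# ----------------------------------------------------------------------

def normalize(table: MetaboliteTable) -> MetaboliteTable:
    """log10 transform then Pareto scale each metabolite column.

    Pareto scaling centres the log10 values and divides by the square
    root of their standard deviation, damping high-variance metabolites
    less aggressively than autoscaling.  Single application only.
    """
    values = table.values
    if values.isna().to_numpy().any():
        raise ValueError("impute before normalising")
    arr = values.to_numpy(dtype=float)
    if np.any(arr <= 0):
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"nonpositive concentration for sample {values.index[i]!r}, "
            f"metabolite {values.columns[j]!r}: log10 undefined"
        )
    logged = np.log10(arr)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    scale = np.sqrt(sd)
    scale[scale == 0] = 1.0  # constant column: centre only
    out = values.copy()
    out.iloc[:, :] = (logged - mean) / scale
    # Pareto output is centred (can be negative): bypass the positivity validator
    normalized = object.__new__(MetaboliteTable)
    normalized.values = out
    normalized.group = table.group
    normalized.diagnosis = table.diagnosis
    normalized.missing_threshold = table.missing_threshold
    return normalized


# ----------------------------------------------------------------------
# Fold changes / volcano / PCA
# ----------------------------------------------------------------------

def fold_changes(
    table: MetaboliteTable, numerator_group: str, denominator_group: str
) -> pd.Series:
    """Per-metabolite ratio of arithmetic group means on the raw scale."""
    num = table.subset(numerator_group).mean(axis=0)
    den = table.subset(denominator_group).mean(axis=0)
    if (den <= 0).any():
        bad = list(den.index[den <= 0])
        raise ValueError(f"denominator group mean <= 0 for: {bad}")
    return num / den


def volcano(
    table: MetaboliteTable,
    fc_threshold: float = 1.5,
    q_threshold: float = 0.05,
    patient_group: str = PATIENT,
    control_group: str = CONTROL,
) -> pd.DataFrame:
    """Patients-vs-controls differential analysis of every metabolite.

    Two-sided Welch t-test on log10 concentrations, Benjamini-Hochberg
    adjustment across the panel; a metabolite is flagged when
    ``|log2 fc| >= log2(fc_threshold)`` and ``q <= q_threshold``, with
    the fold change computed as patients/controls on the raw scale.
    """
    pat = table.subset(patient_group)
    ctl = table.subset(control_group)
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError("each group needs >= 2 samples for the volcano test")
    fc = fold_changes(table, patient_group, control_group)
    _, p = stats.ttest_ind(
        np.log10(pat.to_numpy()), np.log10(ctl.to_numpy()), equal_var=False, axis=0
    )
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    log2fc = np.log2(fc.to_numpy())
    flagged = (np.abs(log2fc) >= np.log2(fc_threshold)) & (q <= q_threshold)
    return pd.DataFrame(
        {
            "fc": fc.to_numpy(),
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "flagged": flagged,
        },
        index=fc.index,
    )


def pca_variance(table: MetaboliteTable, n_components: int) -> np.ndarray:
    """Ordered explained-variance fractions of the normalised table."""
    X = table.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    cap = min(X.shape[0], X.shape[1])
    if n_components > cap:
        raise ValueError(f"n_components {n_components} exceeds min(n, p) = {cap}")
    pca = PCA(n_components=n_components)
    pca.fit(X)
    return pca.explained_variance_ratio_
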