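"""Curated metabolic cellular activities evaluated on patient models.

An activity is the FBA-optimal flux of a designated target reaction,
optionally after knocking out a set of reactions that isolates the
pathway of interest (e.g. blocking oxidative phosphorylation to read
out glycolytic ATP capacity).  Activities saturate at the model's bound
magnitude (1000 by default), so uninformative ones sit constantly at 0
(inactive pathway) or 1000 (fully activated pathway) across a cohort
and are filtered before phenotyping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constrain import PatientModel
from .netcore import fba

__all__ = [
    "ActivityDefinition",
    "read_catalogue",
    "write_catalogue",
    "evaluate_activity",
    "evaluate_matrix",
    "filter_constant",
    "derived_energy_ratios",
    "kruskal_wallis",
]

log = logging.getLogger(__name__)

CONSTANT_TOL = 1e-9


@dataclass(frozen=True)
class ActivityDefinition:
    """One curated activity: optimise ``target_reaction`` under knockouts."""

    name: str
    target_reaction: str
    direction: str = "max"
    knockout_set: tuple[str, ...] = field(default_factory=tuple)
    category: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("max", "min"):
            raise ValueError(f"direction must be max|min, got {self.direction!r}")


def read_catalogue(path: str) -> list[ActivityDefinition]:
    """Load an activity catalogue from JSON (list of definition objects)."""
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for entry in doc:
        out.append(
            ActivityDefinition(
                name=entry["name"],
                target_reaction=entry["target_reaction"],
                direction=entry.get("direction", "max"),
                knockout_set=tuple(entry.get("knockouts", [])),
                category=entry.get("category", ""),
            )
        )
    names = [a.name for a in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate activity names in catalogue")
    return out


def write_catalogue(catalogue: list[ActivityDefinition], path: str) -> None:
    doc = [
        {
            "name": a.name,
            "target_reaction": a.target_reaction,
            "direction": a.direction,
            "knockouts": list(a.knockout_set),
            "category": a.category,
        }
        for a in catalogue
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _validate_catalogue(net, catalogue: list[ActivityDefinition]) -> None:
    rxns = set(net.reaction_ids)
    for act in catalogue:
        missing = ({act.target_reaction} | set(act.knockout_set)) - rxns
        if missing:
            raise ValueError(
                f"activity {act.name!r} references unknown reaction(s): "
                f"{sorted(missing)}"
            )


def evaluate_activity(model: PatientModel, act: ActivityDefinition) -> float:
    """FBA-optimal flux of the activity's target under its knockouts.

    A knockout that leaves the model infeasible reads as an unusable
    pathway: the activity value is 0 (logged), not an exception.
    """
    net = model.network
    _validate_catalogue(net, [act])
    if act.knockout_set:
        net = net.with_bounds({r: (0.0, 0.0) for r in act.knockout_set})
    sol = fba(net, act.target_reaction, act.direction)
    if sol.status != "optimal":
        log.info(
            "activity %s on subject %s: model %s under knockouts -> 0",
            act.name, model.subject_id, sol.status,
        )
        return 0.0
    return sol.objective_value


def evaluate_matrix(
    models: list[PatientModel], catalogue: list[ActivityDefinition]
) -> pd.DataFrame:
    """Subjects x activities matrix of optimal fluxes (one FBA per cell)."""
    if not models or not catalogue:
        raise ValueError("need at least one model and one activity")
    base_shape = models[0].network.S.shape
    for m in models:
        if m.network.S.shape != base_shape or m.network.reaction_ids != models[
            0
        ].network.reaction_ids:
            raise ValueError("all patient models must share one base network")
        _validate_catalogue(m.network, catalogue)
    data = {
        act.name: [evaluate_activity(m, act) for m in models] for act in catalogue
    }
    return pd.DataFrame(data, index=[m.subject_id for m in models])


def filter_constant(
    matrix: pd.DataFrame, tol: float = CONSTANT_TOL
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop activities identical (within ``tol``) across all subjects.

    Returns the filtered matrix and a removal table (activity, constant
    value).  Raises when every activity is constant.
    """
    if matrix.empty:
        raise ValueError("empty activity matrix")
    arr = matrix.to_numpy(dtype=float)
    span = arr.max(axis=0) - arr.min(axis=0)
    const = span <= tol
    removed = pd.DataFrame(
        {
            "activity": matrix.columns[const],
            "constant_value": arr[0, const],
        }
    ).reset_index(drop=True)
    if const.all():
        raise ValueError("all activities constant: nothing to analyse")
    return matrix.loc[:, ~const], removed


def derived_energy_ratios(
    matrix: pd.DataFrame,
    glycolytic: str = "atp_glycolysis",
    overall: str = "atp_overall",
    ratio_name: str = "atp_tca_proportion",
) -> pd.DataFrame:
    """Append the overall/glycolytic ATP ratio per subject.

    The ratio reads the proportion of ATP generation routed through the
    TCA cycle relative to glycolysis; subjects with zero glycolytic ATP
    get a missing (undefined) ratio, logged.
    """
    for col in (glycolytic, overall):
        if col not in matrix.columns:
            raise KeyError(f"activity column {col!r} not in matrix")
    out = matrix.copy()
    g = matrix[glycolytic].to_numpy(dtype=float)
    o = matrix[overall].to_numpy(dtype=float)
    ratio = np.full(len(matrix), np.nan)
    ok = g != 0
    ratio[ok] = o[ok] / g[ok]
    if (~ok).any():
        log.info(
            "ATP ratio undefined (glycolytic ATP = 0) for subjects: %s",
            list(matrix.index[~ok]),
        )
    out[ratio_name] = ratio
    return out


def kruskal_wallis(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Kruskal-Wallis H (tie-corrected) per activity across phenotype groups.

    Returns a table with H, the chi-squared p-value (groups - 1 df) and
    per-group medians.
    """
    labels = pd.Series(labels)
    if not set(labels.index) >= set(matrix.index):
        labels = pd.Series(labels.to_numpy(), index=matrix.index)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    members = {g: matrix.index[labels.loc[matrix.index] == g] for g in groups}
    for g, idx in members.items():
        if len(idx) == 0:
            raise ValueError(f"group {g!r} has no members")
    rows = []
    for act in matrix.columns:
        samples = [matrix.loc[members[g], act].to_numpy() for g in groups]
        if np.ptp(np.concatenate(samples)) <= 1e-12:
            h, p = 0.0, 1.0  # all observations tied: no separation by definition
        else:
            h, p = stats.kruskal(*samples)
        row = {"activity": act, "H": float(h), "p": float(p)}
        for g in groups:
            row[f"median_{g}"] = float(np.median(matrix.loc[members[g], act]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("activity")
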