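"""Patient-contextualised model construction.

Plasma fold changes (patient / healthy-control mean) are mapped onto the
transport reactions that carry the measured metabolites, the baseline
transport-flux quartiles are scaled multiplicatively by those fold
changes, and — when the resulting quartile box excludes every
steady-state flux distribution — the bounds are minimally relaxed by an
elastic linear program (L1-minimal total slack, transport reactions
first) so each patient model is feasible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .netcore import MetabolicNetwork, TransportQuartiles

__all__ = [
    "BoundSet",
    "RelaxationRecord",
    "PatientModel",
    "read_mapping",
    "map_metabolites",
    "build_patient_bounds",
    "relax_to_feasible",
]

SLACK_TOL = 1e-7


@dataclass
class RelaxationRecord:
    """One relaxed bound: which side moved, from where to where."""

    reaction: str
    side: str  # lower | upper
    original: float
    relaxed: float

    @property
    def slack(self) -> float:
        return abs(self.relaxed - self.original)


@dataclass
class PatientModel:
    """A base network plus fold-change-adjusted transport bounds.

    Non-transport bounds always equal the base network's; the constrained
    polytope is nonempty after the recorded relaxations.
    """

    subject_id: str
    network: MetabolicNetwork  # bounds already adjusted (and relaxed)
    bounds: dict[str, tuple[float, float]]  # the pre-relaxation BoundSet
    relaxations: list[RelaxationRecord] = field(default_factory=list)
    fc_provenance: str = "per-patient"  # or per-phenotype

    def to_json(self, path: str) -> None:
        doc = {
            "subject_id": self.subject_id,
            "fc_provenance": self.fc_provenance,
            "bounds": {r: list(b) for r, b in sorted(self.bounds.items())},
            "relaxations": [
                {
                    "reaction": r.reaction,
                    "side": r.side,
                    "original": r.original,
                    "relaxed": r.relaxed,
                    "slack": r.slack,
                }
                for r in self.relaxations
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


# BoundSet is a plain mapping reaction -> (lower, upper)
BoundSet = dict


def read_mapping(path: str) -> pd.DataFrame:
    """Metabolite -> transport-reaction mapping CSV (metabolite_id, reaction_id)."""
    df = pd.read_csv(path)
    need = {"metabolite_id", "reaction_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"mapping CSV must have columns {sorted(need)}")
    return df


def map_metabolites(
    fc: pd.Series | dict,
    mapping: pd.DataFrame,
    net: MetabolicNetwork,
) -> dict[str, float]:
    """Translate per-metabolite fold changes to per-reaction fold changes.

    A transport reaction mapped to several measured metabolites receives
    the arithmetic mean of their fold changes.  Metabolites absent from
    the mapping are reported via a warning and skipped.
    """
    fc = pd.Series(fc, dtype=float)
    transport = set(net.transport_ids)
    bad = set(mapping["reaction_id"]) - transport
    if bad:
        raise ValueError(f"mapping targets non-transport reaction(s): {sorted(bad)}")
    mapped_mets = set(mapping["metabolite_id"])
    unmapped = [m for m in fc.index if m not in mapped_mets]
    if unmapped:
        warnings.warn(
            f"metabolites without a transport mapping (skipped): {unmapped}",
            stacklevel=2,
        )
    per_rxn: dict[str, list[float]] = {}
    for _, row in mapping.iterrows():
        met, rxn = row["metabolite_id"], row["reaction_id"]
        if met in fc.index:
            per_rxn.setdefault(rxn, []).append(float(fc[met]))
    return {rxn: float(np.mean(v)) for rxn, v in per_rxn.items()}


def build_patient_bounds(
    q: TransportQuartiles, rxn_fc: dict[str, float]
) -> BoundSet:
    """Scale baseline quartile bounds by per-reaction fold changes.

    ``lower = fc * q1, upper = fc * q3``; sign-preserving since fc > 0,
    so an uptake interval scales deeper into uptake.  Reactions without a
    fold change keep their baseline ``[q1, q3]``.
    """
    unknown = set(rxn_fc) - set(q.q1)
    if unknown:
        raise KeyError(f"fold changes for reactions without quartiles: {sorted(unknown)}")
    nonpos = {r: v for r, v in rxn_fc.items() if v <= 0}
    if nonpos:
        raise ValueError(f"fold changes must be > 0, got: {nonpos}")
    bounds: BoundSet = {}
    for rxn in q.q1:
        f = rxn_fc.get(rxn, 1.0)
        bounds[rxn] = (f * q.q1[rxn], f * q.q3[rxn])
    return bounds


def _feasible(net: MetabolicNetwork) -> bool:
    res = linprog(
        np.zeros(net.n_reactions),
        A_eq=net.S,
        b_eq=np.zeros(net.n_metabolites),
        bounds=list(zip(net.lb, net.ub)),
        method="highs",
    )
    return res.status == 0


def _elastic_relax(
    net: MetabolicNetwork,
    bounds: BoundSet,
    elastic: list[str],
) -> tuple[list[RelaxationRecord], MetabolicNetwork] | None:
    """Minimise the L1 sum of bound violations over ``elastic`` reactions.

    Returns None when even the fully elastic program is infeasible.
    """
    n = net.n_reactions
    k = len(elastic)
    idx = [net.rxn_index(r) for r in elastic]
    lb = net.lb.copy()
    ub = net.ub.copy()
    for r, (lo, up) in bounds.items():
        j = net.rxn_index(r)
        lb[j], ub[j] = lo, up
    # variables: v (n), s_lo (k), s_up (k); minimise sum of slacks
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    A_eq = np.hstack([net.S, np.zeros((net.n_metabolites, 2 * k))])
    b_eq = np.zeros(net.n_metabolites)
    # v_j + s_lo >= lb_j  and  v_j - s_up <= ub_j  for elastic j
    A_ub = np.zeros((2 * k, n + 2 * k))
    b_ub = np.zeros(2 * k)
    var_bounds: list[tuple[float, float]] = list(zip(lb, ub))
    big = 10.0 * float(np.max(np.abs(np.concatenate([lb, ub])), initial=1.0)) + 1e4
    for t, j in enumerate(idx):
        var_bounds[j] = (-big, big)
        A_ub[t, j] = -1.0
        A_ub[t, n + t] = -1.0
        b_ub[t] = -lb[j]
        A_ub[k + t, j] = 1.0
        A_ub[k + t, n + k + t] = -1.0
        b_ub[k + t] = ub[j]
    var_bounds += [(0.0, None)] * (2 * k)
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=var_bounds, method="highs",
    )
    if res.status != 0:
        return None
    s_lo = res.x[n : n + k]
    s_up = res.x[n + k :]
    records: list[RelaxationRecord] = []
    new_bounds: dict[str, tuple[float, float]] = {}
    for t, r in enumerate(elastic):
        j = idx[t]
        lo, up = lb[j], ub[j]
        if s_lo[t] > SLACK_TOL:
            records.append(RelaxationRecord(r, "lower", lo, lo - s_lo[t]))
            lo = lo - s_lo[t]
        if s_up[t] > SLACK_TOL:
            records.append(RelaxationRecord(r, "upper", up, up + s_up[t]))
            up = up + s_up[t]
        if (lo, up) != (lb[j], ub[j]):
            new_bounds[r] = (lo, up)
    relaxed_net = net.copy()
    for r, (lo, up) in bounds.items():
        j = relaxed_net.rxn_index(r)
        relaxed_net.lb[j], relaxed_net.ub[j] = lo, up
    for r, (lo, up) in new_bounds.items():
        j = relaxed_net.rxn_index(r)
        relaxed_net.lb[j], relaxed_net.ub[j] = lo, up
    return records, relaxed_net


def relax_to_feasible(
    net: MetabolicNetwork,
    bounds: BoundSet,
    subject_id: str = "subject",
    fc_provenance: str = "per-patient",
) -> PatientModel:
    """Apply a BoundSet and minimally relax it to a feasible model.

    A feasible quartile box is applied as-is (empty relaxation log);
    otherwise an elastic LP minimises the total slack, allowing slack on
    transport reactions first and extending to all reactions only when
    transport slack alone cannot restore feasibility.
    """
    constrained = net.with_bounds(bounds)
    if _feasible(constrained):
        return PatientModel(
            subject_id=subject_id,
            network=constrained,
            bounds=dict(bounds),
            relaxations=[],
            fc_provenance=fc_provenance,
        )
    transport_elastic = [r for r in net.transport_ids]
    out = _elastic_relax(net, bounds, transport_elastic)
    if out is None:
        out = _elastic_relax(net, bounds, list(net.reaction_ids))
    if out is None:
        raise ValueError(
            "model infeasible even with all bounds elastic: structurally broken"
        )
    records, relaxed_net = out
    return PatientModel(
        subject_id=subject_id,
        network=relaxed_net,
        bounds=dict(bounds),
        relaxations=records,
        fc_provenance=fc_provenance,
    )
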