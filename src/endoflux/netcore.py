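"""Constraint-based metabolic network core: FBA, FVA, flux sampling, quartiles.

A metabolic network is the steady-state flux polytope ``{v : S v = 0,
lb <= v <= ub}`` over a stoichiometric matrix ``S`` (metabolites x
reactions).  Transport (exchange) reactions carry metabolites across the
cell boundary; by the standard constraint-based convention a negative
transport flux denotes uptake and a positive flux secretion.

All linear programs are solved with the HiGHS solver via
:func:`scipy.optimize.linprog`.  Uniform sampling of the polytope uses a
hit-and-run Markov chain in a null-space parametrisation of ``S v = 0``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

__all__ = [
    "MetabolicNetwork",
    "ObjectiveSolution",
    "FluxSample",
    "TransportQuartiles",
    "read_network",
    "write_network_json",
    "fba",
    "fva",
    "sample_fluxes",
    "transport_quartiles",
    "check_mass_balance",
]

#: contract-level feasibility tolerance (solver works at ~1e-9)
FEAS_TOL = 1e-6
DEFAULT_BOUND = 1000.0

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for elem, num in _FORMULA_RE.findall(formula):
        if elem:
            counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    return counts


@dataclass
class MetabolicNetwork:
    """Stoichiometric network with flux bounds and a transport subset.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Row / column labels of ``S``.
    S
        Stoichiometric coefficient matrix, metabolites x reactions.
    lb, ub
        Per-reaction flux bounds (flux units; default magnitude 1000).
    transport_ids
        Reactions crossing the cell boundary (exchanges / demands).
    formulas
        Optional metabolite formula annotations (e.g. ``"C6N0"``); used
        only for the mass-balance validation of internal reactions.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    transport_ids: list[str] = field(default_factory=list)
    formulas: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    subsystems: dict[str, str] = field(default_factory=dict)
    objective: str | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        m, n = self.S.shape
        if len(self.metabolite_ids) != m:
            raise ValueError(
                f"{len(self.metabolite_ids)} metabolite ids for {m} rows of S"
            )
        if len(self.reaction_ids) != n:
            raise ValueError(
                f"{len(self.reaction_ids)} reaction ids for {n} columns of S"
            )
        if len(set(self.reaction_ids)) != n:
            dup = [r for r in self.reaction_ids if self.reaction_ids.count(r) > 1]
            raise ValueError(f"duplicate reaction id(s): {sorted(set(dup))}")
        if len(set(self.metabolite_ids)) != m:
            raise ValueError("duplicate metabolite ids")
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ValueError("lb/ub length must equal number of reactions")
        if np.any(self.lb > self.ub):
            bad = [self.reaction_ids[i] for i in np.nonzero(self.lb > self.ub)[0]]
            raise ValueError(f"lb > ub for reaction(s): {bad}")
        unknown = set(self.transport_ids) - set(self.reaction_ids)
        if unknown:
            raise ValueError(f"transport_ids not in network: {sorted(unknown)}")
        check_mass_balance(self)

    # -- conveniences ---------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def reversibility(self) -> np.ndarray:
        """Per-reaction flag: True where lb < 0."""
        return self.lb < 0

    def rxn_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"reaction {rxn_id!r} not in network") from None

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            transport_ids=list(self.transport_ids),
            formulas=dict(self.formulas),
            names=dict(self.names),
            subsystems=dict(self.subsystems),
            objective=self.objective,
        )

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicNetwork":
        """Return a copy with ``bounds`` (rxn -> (lb, ub)) applied."""
        net = self.copy()
        for rxn, (lo, up) in bounds.items():
            j = net.rxn_index(rxn)
            net.lb[j], net.ub[j] = lo, up
        if np.any(net.lb > net.ub):
            raise ValueError("applied bounds produce lb > ub")
        return net


def check_mass_balance(net: MetabolicNetwork, tol: float = 1e-9) -> None:
    """Check elemental balance of internal reactions under formula annotations.

    Only reactions touching >= 2 metabolites are checked (single-metabolite
    reactions are boundary sinks/sources by construction), and metabolites
    without a formula annotation are ignored.
    """
    if not net.formulas:
        return
    elem_counts = {m: _parse_formula(f) for m, f in net.formulas.items()}
    transport = set(net.transport_ids)
    for j, rxn in enumerate(net.reaction_ids):
        if rxn in transport:
            continue
        rows = np.nonzero(net.S[:, j])[0]
        if len(rows) < 2:
            continue
        balance: dict[str, float] = {}
        for i in rows:
            met = net.metabolite_ids[i]
            if met not in elem_counts:
                continue
            for elem, cnt in elem_counts[met].items():
                balance[elem] = balance.get(elem, 0.0) + net.S[i, j] * cnt
        bad = {e: b for e, b in balance.items() if abs(b) > tol}
        if bad:
            raise ValueError(f"reaction {rxn!r} is not mass balanced: {bad}")


@dataclass
class ObjectiveSolution:
    """Outcome of one FBA solve.

    ``flux_vector`` is one optimal vertex; alternate optima exist in
    general, so only ``objective_value`` is contractually stable.
    """

    objective_value: float
    flux_vector: np.ndarray | None
    status: str  # optimal | infeasible | unbounded


@dataclass
class FluxSample:
    """Hit-and-run sample of the flux polytope (rows satisfy constraints)."""

    matrix: np.ndarray  # samples x reactions
    reaction_ids: list[str]
    seed: int
    burn_in: int
    thinning: int
    algorithm: str = "hit-and-run (null-space parametrisation)"


@dataclass
class TransportQuartiles:
    """Lower/upper quartiles of transport-reaction marginal flux samples."""

    q1: dict[str, float]
    q3: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.q1) != set(self.q3):
            raise ValueError("q1 and q3 must cover the same reactions")
        for rxn in self.q1:
            if self.q1[rxn] > self.q3[rxn] + 1e-12:
                raise ValueError(f"q1 > q3 for {rxn}")


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_network(path: str, format: str = "json") -> MetabolicNetwork:
    """Load a network from the JSON dialect or from SBML (Level 3 FBC).

    The JSON dialect has top-level keys ``metabolites`` (id, name,
    optional formula), ``reactions`` (id, name, stoichiometry map, lb,
    ub, is_transport, subsystem) and optional ``objective``.
    """
    if format == "json":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def _read_json(path: str) -> MetabolicNetwork:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed network JSON at {path}: {exc}") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ValueError(f"network JSON missing top-level key {key!r}")
    met_ids = [m["id"] for m in doc["metabolites"]]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rxn_ids, transport, formulas, names, subsystems = [], [], {}, {}, {}
    for m in doc["metabolites"]:
        if m.get("formula"):
            formulas[m["id"]] = m["formula"]
        if m.get("name"):
            names[m["id"]] = m["name"]
    n = len(doc["reactions"])
    S = np.zeros((len(met_ids), n))
    lb = np.empty(n)
    ub = np.empty(n)
    for j, r in enumerate(doc["reactions"]):
        rid = r["id"]
        rxn_ids.append(rid)
        for met, coef in r["stoichiometry"].items():
            if met not in met_pos:
                raise ValueError(
                    f"reaction {rid!r} references undeclared metabolite {met!r}"
                )
            S[met_pos[met], j] = float(coef)
        reversible = bool(r.get("reversible", "lb" in r and r["lb"] < 0))
        lb[j] = r.get("lb", -DEFAULT_BOUND if reversible else 0.0)
        ub[j] = r.get("ub", DEFAULT_BOUND)
        if r.get("is_transport"):
            transport.append(rid)
        if r.get("name"):
            names[rid] = r["name"]
        if r.get("subsystem"):
            subsystems[rid] = r["subsystem"]
    return MetabolicNetwork(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        transport_ids=transport,
        formulas=formulas,
        names=names,
        subsystems=subsystems,
        objective=doc.get("objective"),
    )


def write_network_json(net: MetabolicNetwork, path: str) -> None:
    doc = {
        "metabolites": [
            {
                "id": m,
                **({"name": net.names[m]} if m in net.names else {}),
                **({"formula": net.formulas[m]} if m in net.formulas else {}),
            }
            for m in net.metabolite_ids
        ],
        "reactions": [],
        "objective": net.objective,
    }
    transport = set(net.transport_ids)
    for j, rxn in enumerate(net.reaction_ids):
        rows = np.nonzero(net.S[:, j])[0]
        doc["reactions"].append(
            {
                "id": rxn,
                **({"name": net.names[rxn]} if rxn in net.names else {}),
                "stoichiometry": {
                    net.metabolite_ids[i]: float(net.S[i, j]) for i in rows
                },
                "lb": float(net.lb[j]),
                "ub": float(net.ub[j]),
                "is_transport": rxn in transport,
                **(
                    {"subsystem": net.subsystems[rxn]}
                    if rxn in net.subsystems
                    else {}
                ),
            }
        )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _read_sbml(path: str) -> MetabolicNetwork:
    # cobrapy (libsbml backend) handles the SBML/FBC dialect
    from cobra.io import read_sbml_model

    model = read_sbml_model(path)
    return from_cobra(model)


def from_cobra(model) -> MetabolicNetwork:
    """Convert a cobrapy model to a :class:`MetabolicNetwork`."""
    met_ids = [m.id for m in model.metabolites]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rxn_ids = [r.id for r in model.reactions]
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    transport = [r.id for r in model.reactions if r.boundary]
    formulas = {m.id: m.formula for m in model.metabolites if m.formula}
    for j, r in enumerate(model.reactions):
        for met, coef in r.metabolites.items():
            S[met_pos[met.id], j] = coef
        lb[j], ub[j] = r.lower_bound, r.upper_bound
    return MetabolicNetwork(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        transport_ids=transport,
        formulas=formulas,
    )


def to_cobra(net: MetabolicNetwork, model_id: str = "model"):
    """Convert to a cobrapy model (e.g. for SBML export or cross-checks)."""
    import cobra

    model = cobra.Model(model_id)
    # lumped formula annotations are deliberately not exported to SBML
    mets = {m: cobra.Metabolite(m, compartment="c") for m in net.metabolite_ids}
    rxns = []
    for j, rid in enumerate(net.reaction_ids):
        r = cobra.Reaction(rid)
        # plain floats: libsbml rejects numpy scalars downstream
        r.lower_bound, r.upper_bound = float(net.lb[j]), float(net.ub[j])
        rows = np.nonzero(net.S[:, j])[0]
        r.add_metabolites(
            {mets[net.metabolite_ids[i]]: net.S[i, j] for i in rows}
        )
        rxns.append(r)
    model.add_reactions(rxns)
    if net.objective is not None:
        model.objective = net.objective
    return model


# ----------------------------------------------------------------------
# Linear-program flux analysis
# ----------------------------------------------------------------------

def _solve_lp(net: MetabolicNetwork, c: np.ndarray) -> ObjectiveSolution:
    res = linprog(
        c,
        A_eq=net.S,
        b_eq=np.zeros(net.n_metabolites),
        bounds=list(zip(net.lb, net.ub)),
        method="highs",
    )
    if res.status == 0:
        return ObjectiveSolution(
            objective_value=float(res.fun), flux_vector=res.x, status="optimal"
        )
    if res.status == 2:
        return ObjectiveSolution(np.nan, None, "infeasible")
    if res.status == 3:
        return ObjectiveSolution(np.nan, None, "unbounded")
    raise RuntimeError(f"LP solver failure: {res.message}")


def fba(
    net: MetabolicNetwork, objective_rxn: str, direction: str = "max"
) -> ObjectiveSolution:
    """Optimise the flux of one reaction over the steady-state polytope."""
    if net.n_reactions == 0:
        raise ValueError("empty network")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    j = net.rxn_index(objective_rxn)
    c = np.zeros(net.n_reactions)
    c[j] = -1.0 if direction == "max" else 1.0
    sol = _solve_lp(net, c)
    if sol.status == "optimal":
        sol.objective_value = float(sol.flux_vector[j])
        resid = np.abs(net.S @ sol.flux_vector).max() if net.n_metabolites else 0.0
        if resid > FEAS_TOL:
            raise RuntimeError(f"FBA solution violates Sv=0 (residual {resid:g})")
    return sol


def fva(net: MetabolicNetwork, rxn: str) -> tuple[float, float]:
    """Minimum and maximum achievable flux of one reaction."""
    lo = fba(net, rxn, "min")
    hi = fba(net, rxn, "max")
    if lo.status != "optimal" or hi.status != "optimal":
        raise ValueError(f"FVA failed for {rxn}: network {lo.status}/{hi.status}")
    return lo.objective_value, hi.objective_value


# ----------------------------------------------------------------------
# Hit-and-run sampling
# ----------------------------------------------------------------------

def _null_space_basis(S: np.ndarray) -> np.ndarray:
    if S.size == 0:
        return np.eye(S.shape[1])
    return linalg.null_space(S)


def _interior_point(net: MetabolicNetwork, N: np.ndarray) -> np.ndarray:
    """Strictly interior point of the polytope along non-degenerate directions.

    Maximises a common slack t with per-reaction caps so that reactions
    fixed by stoichiometry (zero null-space row) or by lb == ub do not
    block positivity of t.
    """
    n, d = N.shape
    achievable = np.abs(N).max(axis=1) > 1e-10 if d else np.zeros(n, bool)
    delta = np.minimum(1.0, (net.ub - net.lb) / 2.0)
    delta[~achievable] = 0.0
    # variables: u (d), t (1); maximise t
    c = np.zeros(d + 1)
    c[-1] = -1.0
    # lb + t*delta <= N u  ->  -N u + t*delta <= -lb
    # N u <= ub - t*delta  ->   N u + t*delta <= ub
    A_ub = np.vstack(
        [
            np.hstack([-N, delta[:, None]]),
            np.hstack([N, delta[:, None]]),
        ]
    )
    b_ub = np.concatenate([-net.lb, net.ub])
    span = float(np.max(net.ub - net.lb, initial=1.0))
    bounds = [(-1e7, 1e7)] * d + [(0.0, span)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status == 2:
        raise ValueError("flux polytope is empty: cannot sample")
    if res.status != 0:
        raise RuntimeError(f"interior-point LP failed: {res.message}")
    u = res.x[:d]
    return N @ u


def sample_fluxes(
    net: MetabolicNetwork,
    n: int,
    seed: int,
    burn_in: int = 1000,
    thinning: int = 10,
) -> FluxSample:
    """Draw ``n`` approximately uniform flux vectors by hit-and-run.

    The chain runs in the null-space parametrisation of ``S v = 0`` so
    every iterate satisfies the steady-state constraint exactly (up to
    round-off); bounds are enforced by the line-segment step.  Identical
    seeds give identical matrices.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.any(~np.isfinite(net.lb)) or np.any(~np.isfinite(net.ub)):
        raise ValueError("polytope must be bounded (finite lb/ub) for sampling")
    N = _null_space_basis(net.S)
    d = N.shape[1]
    x = _interior_point(net, N)
    if d == 0:
        return FluxSample(
            np.tile(x, (n, 1)), list(net.reaction_ids), seed, burn_in, thinning
        )
    rng = np.random.default_rng(seed)
    lb, ub = net.lb, net.ub
    out = np.empty((n, net.n_reactions))
    kept = 0
    step = 0
    total = burn_in + n * thinning
    eps = 1e-12
    while kept < n:
        z = rng.standard_normal(d)
        dvec = N @ z
        nrm = np.linalg.norm(dvec)
        if nrm < 1e-12:
            continue
        dvec /= nrm
        # segment of feasibility along x + t*dvec
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lb - x) / dvec
            t_hi = (ub - x) / dvec
        pos = dvec > eps
        neg = dvec < -eps
        tmax = np.inf
        tmin = -np.inf
        if pos.any():
            tmax = min(tmax, t_hi[pos].min())
            tmin = max(tmin, t_lo[pos].max())
        if neg.any():
            tmax = min(tmax, t_lo[neg].min())
            tmin = max(tmin, t_hi[neg].max())
        if not np.isfinite(tmin) or not np.isfinite(tmax) or tmax < tmin:
            step += 1
            continue
        x = x + rng.uniform(tmin, tmax) * dvec
        # guard against round-off drift outside the box
        np.clip(x, lb, ub, out=x)
        step += 1
        if step > burn_in and (step - burn_in) % thinning == 0:
            out[kept] = x
            kept += 1
        if step > 10 * total + 1000:
            raise RuntimeError("hit-and-run failed to advance; polytope degenerate")
    return FluxSample(out, list(net.reaction_ids), seed, burn_in, thinning)


def transport_quartiles(
    sample: FluxSample, transport_ids: list[str]
) -> TransportQuartiles:
    """Q1/Q3 of each transport reaction's marginal flux distribution.

    Uses the linear-interpolation (type-7) quantile convention.
    """
    if sample.matrix.shape[0] < 4:
        raise ValueError("need at least 4 sample rows for quartiles")
    pos = {r: j for j, r in enumerate(sample.reaction_ids)}
    missing = [r for r in transport_ids if r not in pos]
    if missing:
        raise KeyError(f"reactions absent from sample: {missing}")
    q1, q3 = {}, {}
    for r in transport_ids:
        col = sample.matrix[:, pos[r]]
        lo, hi = np.percentile(col, [25.0, 75.0])  # type-7 / linear
        q1[r], q3[r] = float(lo), float(hi)
    return TransportQuartiles(q1=q1, q3=q3)
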