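"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's LP/elastic code paths: vertices
are enumerated combinatorially, relaxation minima come from grid search,
and permutation nulls are generated directly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def enumerate_vertices(S, lb, ub, tol=1e-9):
    """All vertices of {Sv=0, lb<=v<=ub} by active-bound enumeration.

    Feasible only for tiny networks: every size-d subset of reactions
    (d = n - rank(S)) is pinned to a bound combination and the remaining
    fluxes solved from the steady-state equations.
    """
    S = np.asarray(S, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    d = n - rank
    vertices = []
    for pinned in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in pinned]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in pinned]):
            v = np.full(n, np.nan)
            for j, val in zip(pinned, choice):
                v[j] = val
            rhs = -S[:, list(pinned)] @ np.array(choice) if pinned else np.zeros(
                S.shape[0]
            )
            A = S[:, free]
            if free:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                if np.linalg.norm(A @ sol - rhs) > 1e-7:
                    continue
                v[free] = sol
            elif np.linalg.norm(rhs) > 1e-7:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(np.clip(v, lb, ub))
    return np.array(vertices)


def vertex_optimum(net, rxn_id, direction="max"):
    """LP optimum of one flux by explicit vertex enumeration."""
    verts = enumerate_vertices(net.S, net.lb, net.ub)
    if len(verts) == 0:
        raise ValueError("no vertices: infeasible or degenerate fixture")
    j = net.reaction_ids.index(rxn_id)
    vals = verts[:, j]
    return float(vals.max() if direction == "max" else vals.min())


def _feasible_with(net, bounds, tol=1e-9):
    lb = net.lb.copy()
    ub = net.ub.copy()
    for r, (lo, up) in bounds.items():
        j = net.reaction_ids.index(r)
        lb[j], ub[j] = lo, up
    res = linprog(
        np.zeros(net.n_reactions),
        A_eq=net.S,
        b_eq=np.zeros(net.n_metabolites),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.status == 0


def grid_min_single_relaxation(net, bounds, max_slack=10.0, step=0.01):
    """Smallest single-bound slack restoring feasibility, by grid search.

    Valid as a total-slack oracle only on fixtures where one relaxed
    bound suffices.  Returns np.inf when no single bound works.
    """
    best = np.inf
    grid = np.arange(step, max_slack + step, step)
    for rxn in bounds:
        lo, up = bounds[rxn]
        for slack in grid:
            if slack >= best:
                break
            trial = dict(bounds)
            trial[rxn] = (lo - slack, up)
            if _feasible_with(net, trial):
                best = min(best, slack)
                break
        for slack in grid:
            if slack >= best:
                break
            trial = dict(bounds)
            trial[rxn] = (lo, up + slack)
            if _feasible_with(net, trial):
                best = min(best, slack)
                break
    return best


def kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H, computed from the rank formula."""
    from scipy.stats import rankdata

    data = np.concatenate(groups)
    ranks = rankdata(data)
    N = len(data)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(data, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (N**3 - N)
    return h / correction


def kruskal_permutation_p(groups, n_perm=100_000, seed=0):
    """Monte-Carlo permutation p-value of the tie-corrected H (vectorised)."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    data = np.concatenate(groups)
    N = len(data)
    h_obs = kruskal_h(groups)
    # permute via random keys; ranks recomputed per permutation
    keys = rng.random((n_perm, N))
    perms = data[np.argsort(keys, axis=1)]
    ranks = rankdata(perms, axis=1)
    h = np.zeros(n_perm)
    start = 0
    for s in sizes:
        h += ranks[:, start : start + s].sum(axis=1) ** 2 / s
        start += s
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(data, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (N**3 - N)
    h /= correction
    return float((h >= h_obs - 1e-12).mean())
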