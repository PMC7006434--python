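"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path: vertex enumeration works
directly on (S, lb, ub) arrays, and the blocked-reaction oracle assembles its
own matrices and calls scipy's linprog directly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

FEAS_TOL = 1e-9


def assemble_matrix(reactions: list[dict], met_order: list[str]) -> np.ndarray:
    """Entry-by-entry dense assembly from per-reaction stoichiometry maps."""
    S = np.zeros((len(met_order), len(reactions)))
    index = {m: i for i, m in enumerate(met_order)}
    for j, rxn in enumerate(reactions):
        for met, coef in rxn["stoichiometry"].items():
            S[index[met], j] = coef
    return S


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-8) -> list[np.ndarray]:
    """All vertices of {v : S v = 0, lb <= v <= ub} by active-set brute force.

    A vertex has n linearly independent active constraints; with rank(S) = r
    equalities, n - r variables sit at a bound.  Enumerate every choice of
    fixed variables and bound side, solve for the free ones, keep unique
    feasible solutions.  Exponential — only for n <= ~8.
    """
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - r
    vertices: list[np.ndarray] = []
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if np.linalg.matrix_rank(A) < len(free):
            continue  # free block underdetermined: no isolated solution
        for sides in itertools.product((0, 1), repeat=n_fixed):
            v = np.empty(n)
            for j, side in zip(fixed, sides):
                v[j] = ub[j] if side else lb[j]
            if not np.all(np.isfinite(v[list(fixed)])):
                continue
            rhs = -S[:, list(fixed)] @ v[list(fixed)] if n_fixed else np.zeros(m)
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > tol * 10:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if not any(np.allclose(v, w, atol=tol * 10) for w in vertices):
                vertices.append(v)
    return vertices


def brute_force_optimum(S, lb, ub, c, direction="max"):
    """Optimum of c·v over the enumerated vertex set (None if infeasible)."""
    vertices = enumerate_vertices(np.asarray(S, float), np.asarray(lb, float),
                                  np.asarray(ub, float))
    if not vertices:
        return None
    values = [float(np.dot(c, v)) for v in vertices]
    return max(values) if direction == "max" else min(values)


def lp_flux_range(reactions: list[dict], met_order: list[str], j: int):
    """(min, max) flux of reaction j via direct scipy linprog calls."""
    S = assemble_matrix(reactions, met_order)
    bounds = [(r["lb"], r["ub"]) for r in reactions]
    c = np.zeros(len(reactions))
    c[j] = 1.0
    lo = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    hi = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if lo.status != 0 or hi.status != 0:
        return None
    return lo.fun, -hi.fun


def blocked_by_reachability_and_lp(reactions: list[dict], met_order: list[str]) -> set[str]:
    """Blocked-reaction oracle: reachability prefilter plus per-reaction LP.

    A reaction consuming a metabolite no open reaction can supply is blocked
    outright; every other reaction is checked by maximizing |flux| directly.
    """
    # Reachability: metabolites producible starting from the exchanged ones.
    # Each orientation of a reaction can fire once its inputs are producible.
    producible: set[str] = set()
    for rxn in reactions:
        if len(rxn["stoichiometry"]) == 1:
            producible.update(rxn["stoichiometry"])

    def _directions(rxn):
        consumed = {m for m, coef in rxn["stoichiometry"].items() if coef < 0}
        produced = {m for m, coef in rxn["stoichiometry"].items() if coef > 0}
        dirs = []
        if rxn["ub"] > 0:
            dirs.append((consumed, produced))
        if rxn["lb"] < 0:
            dirs.append((produced, consumed))
        return dirs

    changed = True
    while changed:
        changed = False
        for rxn in reactions:
            for inputs, outputs in _directions(rxn):
                if inputs <= producible and not outputs <= producible:
                    producible |= outputs
                    changed = True

    blocked = set()
    for j, rxn in enumerate(reactions):
        if len(rxn["stoichiometry"]) > 1:
            runnable = any(
                inputs <= producible for inputs, _ in _directions(rxn)
            )
            if not runnable:
                blocked.add(rxn["id"])
                continue
        rng = lp_flux_range(reactions, met_order, j)
        if rng is None or (abs(rng[0]) <= FEAS_TOL and abs(rng[1]) <= FEAS_TOL):
            blocked.add(rxn["id"])
    return blocked
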