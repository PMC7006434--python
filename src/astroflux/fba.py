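"""Linear-programming core: FBA, lexicographic FBA, parsimonious
canonicalization, flux variability, blocked-reaction detection, knockouts.

All solves go through scipy's HiGHS backend (:func:`scipy.optimize.linprog`)
with fixed variable ordering, which makes repeated solves deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import InfeasibleModelError, ModelStructureError, SolverError
from .model import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "FluxDistribution",
    "solve_fba",
    "solve_lexicographic",
    "canonical_fluxes",
    "flux_variability",
    "find_blocked_reactions",
    "knockout",
    "mass_balance_residual",
]

FEASIBILITY_TOL = 1e-9
LEX_TOL = 1e-6


@dataclass
class FluxDistribution:
    """Solver status plus the flux vector v (one entry per reaction)."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None
    fluxes: dict[str, float]
    objective_id: str | None
    stage_values: list[float] = field(default_factory=list)
    failed_stage: int | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _run_lp(c, A_eq, b_eq, A_ub, b_ub, bounds):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failed: {res.message}")
    return status, res


def _model_arrays(model: MetabolicModel):
    S = model.S
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, bounds


def _objective_vector(model: MetabolicModel, objective_id: str) -> np.ndarray:
    c = np.zeros(model.n_reactions)
    c[model.reaction_ids().index(objective_id)] = 1.0
    return c


def _as_distribution(model, status, res, objective_id, sign):
    if status != "optimal":
        return FluxDistribution(status, None, {}, objective_id)
    fluxes = dict(zip(model.reaction_ids(), res.x))
    return FluxDistribution(status, sign * res.fun, fluxes, objective_id)


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
) -> FluxDistribution:
    """Optimize one reaction's flux subject to S·v = 0 and the bounds."""
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ModelStructureError("no objective reaction given and model has none")
    model.reaction(objective_id)
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    S, bounds = _model_arrays(model)
    c = _objective_vector(model, objective_id)
    sign = -1.0 if direction == "max" else 1.0
    status, res = _run_lp(sign * c, S, np.zeros(S.shape[0]), None, None, bounds)
    return _as_distribution(model, status, res, objective_id, sign)


def solve_lexicographic(
    model: MetabolicModel,
    objectives: list[str],
    tol: float = LEX_TOL,
) -> FluxDistribution:
    """Maximize objectives in order, fixing each optimum before the next.

    Stage k maximizes objective k subject to every previous objective being
    within relative tolerance *tol* of its optimum.  On infeasibility the
    returned distribution carries ``failed_stage``.
    """
    if not objectives:
        raise ValueError("at least one objective is required")
    for rxn_id in objectives:
        model.reaction(rxn_id)
    S, bounds = _model_arrays(model)
    b_eq = np.zeros(S.shape[0])
    ub_rows: list[np.ndarray] = []
    ub_vals: list[float] = []
    stage_values: list[float] = []
    res = None
    for k, rxn_id in enumerate(objectives):
        c = _objective_vector(model, rxn_id)
        A_ub = np.vstack(ub_rows) if ub_rows else None
        b_ub = np.array(ub_vals) if ub_rows else None
        status, res = _run_lp(-c, S, b_eq, A_ub, b_ub, bounds)
        if status != "optimal":
            return FluxDistribution(status, None, {}, rxn_id, stage_values, failed_stage=k)
        opt = -res.fun
        stage_values.append(opt)
        slack = tol * max(1.0, abs(opt))
        ub_rows.append(-c)
        ub_vals.append(-(opt - slack))
    fluxes = dict(zip(model.reaction_ids(), res.x))
    return FluxDistribution("optimal", stage_values[-1], fluxes, objectives[-1], stage_values)


def canonical_fluxes(
    model: MetabolicModel,
    objective_id: str | list[str] | None = None,
    tol: float = LEX_TOL,
) -> FluxDistribution:
    """Deterministic parsimonious flux vector.

    First fixes the optimum of each objective (lexicographically when a list
    is given), then minimizes total absolute flux Σ|v_j| among the remaining
    optima.  The result is reproducible across calls: fixed variable order,
    fixed solver, no randomized tie-breaking.
    """
    if objective_id is None:
        objective_id = model.objective_id
    objectives = [objective_id] if isinstance(objective_id, str) else list(objective_id)
    lex = solve_lexicographic(model, objectives, tol=tol)
    if not lex.optimal:
        return lex

    n = model.n_reactions
    S, bounds = _model_arrays(model)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    # v = p - m with p, m >= 0; minimize sum(p + m).
    p_bounds = list(zip(np.maximum(lb, 0.0), np.maximum(ub, 0.0)))
    m_bounds = list(zip(np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)))
    A_eq = sparse.hstack([S, -S]).tocsc()
    b_eq = np.zeros(S.shape[0])
    ub_rows, ub_vals = [], []
    for rxn_id, opt in zip(objectives, lex.stage_values):
        c = _objective_vector(model, rxn_id)
        slack = tol * max(1.0, abs(opt))
        ub_rows.append(np.concatenate([-c, c]))
        ub_vals.append(-(opt - slack))
    status, res = _run_lp(
        np.ones(2 * n),
        A_eq,
        b_eq,
        np.vstack(ub_rows),
        np.array(ub_vals),
        p_bounds + m_bounds,
    )
    if status != "optimal":  # should not happen: lex point is feasible
        raise SolverError(f"parsimonious stage unexpectedly {status}")
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(model.reaction_ids(), v))
    return FluxDistribution("optimal", lex.stage_values[-1], fluxes, objectives[-1],
                            lex.stage_values)


def flux_variability(
    model: MetabolicModel,
    objective_id: str | None = None,
    fraction: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux subject to objective ≥ fraction × optimum.

    With ``objective_id=None`` the variability of the whole feasible region
    is computed (no objective constraint).
    """
    S, bounds = _model_arrays(model)
    b_eq = np.zeros(S.shape[0])
    A_ub = b_ub = None
    if objective_id is not None:
        base = solve_fba(model, objective_id, "max")
        if not base.optimal:
            raise InfeasibleModelError(
                f"model is {base.status}; cannot run flux variability"
            )
        c = _objective_vector(model, objective_id)
        A_ub = -c[np.newaxis, :]
        b_ub = np.array([-fraction * base.objective_value])
    out: dict[str, tuple[float, float]] = {}
    n = model.n_reactions
    for j, rxn in enumerate(model.reactions):
        c = np.zeros(n)
        c[j] = 1.0
        lo_status, lo = _run_lp(c, S, b_eq, A_ub, b_ub, bounds)
        hi_status, hi = _run_lp(-c, S, b_eq, A_ub, b_ub, bounds)
        if lo_status != "optimal" or hi_status != "optimal":
            raise InfeasibleModelError(
                f"flux variability subproblem for {rxn.id!r} is {lo_status}/{hi_status}"
            )
        out[rxn.id] = (lo.fun, -hi.fun)
    return out


def find_blocked_reactions(model: MetabolicModel, tol: float = FEASIBILITY_TOL) -> set[str]:
    """Reactions that cannot carry flux even with all exchanges fully open."""
    opened = model.copy()
    for rxn in opened.reactions:
        if rxn.kind == "exchange":
            rxn.bounds = (-DEFAULT_BOUND, DEFAULT_BOUND)
    ranges = flux_variability(opened, objective_id=None)
    return {
        rxn_id
        for rxn_id, (vmin, vmax) in ranges.items()
        if abs(vmin) <= tol and abs(vmax) <= tol
    }


def knockout(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Copy of *model* with the reaction's bounds fixed to zero."""
    model.reaction(reaction_id)  # raises on unknown id
    ko = model.copy()
    ko.reaction(reaction_id).bounds = (0.0, 0.0)
    return ko


def mass_balance_residual(model: MetabolicModel, fluxes: dict[str, float]) -> float:
    """‖S·v‖∞ for a flux dict over the model's reactions."""
    v = np.array([fluxes.get(r.id, 0.0) for r in model.reactions])
    return float(np.abs(model.S @ v).max()) if model.n_reactions else 0.0
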