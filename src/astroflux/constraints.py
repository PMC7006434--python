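"""Tissue-specific constraining of a metabolic model.

Expression-proportional bounds via GPR scores (AND = min of subunits,
OR = sum of isoenzymes), additionCost-style gap filling against a reference
reaction set, and medium application with the COBRA sign convention
(uptake = negative flux on the exchange reaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DegenerateProfileError, ModelStructureError
from .fba import FEASIBILITY_TOL, solve_fba
from .gpr import GPR
from .io.tables import ExpressionProfile, Medium
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "GapFillResult",
    "evaluate_gpr",
    "apply_expression_bounds",
    "addition_cost",
    "gap_fill",
    "apply_medium",
    "resolve_exchange_id",
]


def evaluate_gpr(gpr: GPR, profile: ExpressionProfile) -> float | None:
    """Score a GPR against an expression profile.

    Leaves map to the gene's expression (0 when absent), AND nodes take the
    minimum of their children, OR nodes the sum.  An empty GPR returns
    ``None`` ("no association").
    """
    if gpr.is_empty:
        return None
    if gpr.kind == "leaf":
        return profile.get(gpr.gene, 0.0)
    child_scores = [evaluate_gpr(c, profile) for c in gpr.children]
    if gpr.kind == "and":
        return min(child_scores)
    return sum(child_scores)


def apply_expression_bounds(
    model: MetabolicModel,
    profile: ExpressionProfile,
    bound_cap: float = 1000.0,
) -> MetabolicModel:
    """Rescale bounds proportionally to GPR scores.

    Each GPR-bearing non-exchange reaction gets ``ub = bound_cap · s/s_max``
    (and ``lb = -ub`` if reversible, else 0).  Reactions without gene
    association and exchange reactions keep their bounds.  Uniformly scaling
    the profile leaves the result unchanged.
    """
    scores: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.kind == "exchange":
            continue
        score = evaluate_gpr(rxn.gpr, profile)
        if score is not None:
            scores[rxn.id] = score
    if scores and max(scores.values()) <= 0.0:
        raise DegenerateProfileError("all GPR scores are zero over this model")

    constrained = model.copy()
    if not scores:
        return constrained
    s_max = max(scores.values())
    for rxn_id, score in scores.items():
        rxn = constrained.reaction(rxn_id)
        ub = bound_cap * score / s_max
        rxn.bounds = (-ub if rxn.reversible else 0.0, ub)
    return constrained


def addition_cost(candidate: Reaction, model: MetabolicModel) -> float:
    """Fraction of the candidate's metabolites absent from the model ∈ [0, 1]."""
    if not candidate.stoichiometry:
        raise ModelStructureError(f"candidate {candidate.id!r} has empty stoichiometry")
    met_ids = list(candidate.stoichiometry)
    absent = sum(1 for m in met_ids if not model.has_metabolite(m))
    return absent / len(met_ids)


@dataclass
class GapFillResult:
    """Ordered additions made by :func:`gap_fill` plus the outcome flag."""

    added: list[str] = field(default_factory=list)
    costs: dict[str, float] = field(default_factory=dict)
    feasible: bool = False
    rounds: int = 0


def gap_fill(
    model: MetabolicModel,
    reference: list[Reaction],
    objective_id: str,
    cost_threshold: float = 0.25,
    max_rounds: int = 100,
) -> tuple[MetabolicModel, GapFillResult]:
    """Add cheap reference reactions until the objective carries flux.

    Each round adds every not-yet-added reference reaction whose
    :func:`addition_cost` against the current model is ≤ *cost_threshold*,
    then re-optimizes.  Terminates when the objective optimum exceeds the
    feasibility tolerance, the pool is exhausted, or *max_rounds* is hit.
    Returns the (possibly extended) model copy and a :class:`GapFillResult`.
    """
    overlap = [r.id for r in reference if model.has_reaction(r.id)]
    if overlap:
        raise ModelStructureError(f"reference overlaps model reactions: {overlap}")
    work = model.copy()
    result = GapFillResult()
    pool = {r.id: r for r in reference}

    def _objective_open() -> bool:
        sol = solve_fba(work, objective_id, "max")
        return sol.optimal and sol.objective_value > FEASIBILITY_TOL

    while result.rounds < max_rounds:
        if _objective_open():
            result.feasible = True
            break
        if not pool:
            break
        result.rounds += 1
        batch = []
        for rxn_id in sorted(pool):
            cost = addition_cost(pool[rxn_id], work)
            if cost <= cost_threshold:
                batch.append((rxn_id, cost))
        if not batch:
            break
        for rxn_id, cost in batch:
            rxn = pool.pop(rxn_id)
            for met_id in rxn.stoichiometry:
                if not work.has_metabolite(met_id):
                    work.add_metabolite(Metabolite(id=met_id))
            rxn.kind = None  # reclassify in the target model
            work.add_reaction(rxn)
            result.added.append(rxn_id)
            result.costs[rxn_id] = cost
    else:
        result.feasible = _objective_open()
        return work, result

    if not result.feasible:
        result.feasible = _objective_open()
    return work, result


def _normalize_alias(rxn_id: str) -> str:
    """Canonical key for exchange-id dialects: ``EXhdca(e)`` == ``EX_hdca_e``."""
    return "".join(ch for ch in rxn_id.lower() if ch.isalnum())


def resolve_exchange_id(model: MetabolicModel, rxn_id: str) -> str:
    """Resolve an exchange id, accepting dialect aliases."""
    if model.has_reaction(rxn_id):
        return rxn_id
    wanted = _normalize_alias(rxn_id)
    matches = [r.id for r in model.reactions if _normalize_alias(r.id) == wanted]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise ModelStructureError(f"no reaction matching exchange id {rxn_id!r}")
    raise ModelStructureError(f"ambiguous exchange id {rxn_id!r}: {matches}")


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Constrain exchange reactions to the medium definition.

    Listed inputs get ``lb = -max_uptake``; allowed outputs keep a positive
    upper bound; every other exchange is closed to (0, 0).
    """
    constrained = model.copy()
    uptake_ids = {resolve_exchange_id(constrained, k): v for k, v in medium.uptake.items()}
    output_ids = {resolve_exchange_id(constrained, k) for k in medium.outputs}
    for rxn_id in list(uptake_ids) + list(output_ids):
        rxn = constrained.reaction(rxn_id)
        if rxn.kind != "exchange":
            raise ModelStructureError(
                f"medium id {rxn_id!r} resolves to a {rxn.kind} reaction, not an exchange"
            )
    for rxn in constrained.reactions:
        if rxn.kind != "exchange":
            continue
        is_input = rxn.id in uptake_ids
        is_output = rxn.id in output_ids
        lb = -uptake_ids[rxn.id] if is_input else 0.0
        if is_input or is_output:
            ub = max(rxn.upper_bound, 0.0)
        else:
            ub = 0.0
        rxn.bounds = (lb, ub)
    return constrained
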