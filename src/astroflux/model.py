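"""Core domain types for compartmentalized metabolic networks.

A :class:`MetabolicModel` owns ordered collections of metabolites and
reactions and can assemble the m-by-n stoichiometric matrix ``S`` whose
column j holds the coefficients of reaction j (negative = consumed).
Flux units throughout are mmol·gDW⁻¹·h⁻¹.
"""

from __future__ import annotations

import copy
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import ModelStructureError
from .gpr import GPR

__all__ = [
    "COMPARTMENTS",
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ValidationReport",
    "parse_metabolite_id",
    "normalize_metabolite_id",
    "parse_formula",
    "build_stoichiometric_matrix",
    "classify_reaction",
    "validate_model",
]

#: Allowed one-letter compartment codes: cytosol, mitochondrion,
#: extracellular, Golgi, endoplasmic reticulum, lysosome, nucleus, peroxisome.
COMPARTMENTS = frozenset("cmegrlnx")

#: Default magnitude for unbounded fluxes.
DEFAULT_BOUND = 1000.0

_BRACKET_ID = re.compile(r"^(?P<base>\S+?)\[(?P<comp>[a-z])\]$")
_SUFFIX_ID = re.compile(r"^(?P<base>\S+?)_(?P<comp>[cmegrlnx])$")


def parse_metabolite_id(met_id: str) -> tuple[str, str]:
    """Split ``"glu_L[e]"`` into ``("glu_L", "e")``.

    Raises :class:`ModelStructureError` for ids that do not parse or carry
    an unknown compartment code.
    """
    m = _BRACKET_ID.match(met_id)
    if m is None:
        raise ModelStructureError(f"metabolite id {met_id!r} is not of base[compartment] form")
    base, comp = m.group("base"), m.group("comp")
    if comp not in COMPARTMENTS:
        raise ModelStructureError(f"metabolite id {met_id!r} has unknown compartment {comp!r}")
    return base, comp


def normalize_metabolite_id(met_id: str) -> str:
    """Normalize either dialect (``glu_L[e]`` or ``glu_L_e``) to bracket form."""
    if _BRACKET_ID.match(met_id):
        return met_id
    m = _SUFFIX_ID.match(met_id)
    if m is not None:
        return f"{m.group('base')}[{m.group('comp')}]"
    raise ModelStructureError(f"metabolite id {met_id!r} matches neither bracket nor suffix dialect")


_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula (``"C6H12O6"``) into element counts.

    Fictional one/two-letter elements are accepted; parentheses are not.
    """
    counts: dict[str, float] = defaultdict(float)
    pos = 0
    while pos < len(formula):
        m = _ELEMENT.match(formula, pos)
        if m is None or m.end() == pos:
            raise ModelStructureError(f"cannot parse formula {formula!r} at position {pos}")
        counts[m.group(1)] += float(m.group(2)) if m.group(2) else 1.0
        pos = m.end()
    return dict(counts)


@dataclass
class Metabolite:
    """A chemical species located in one compartment."""

    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self):
        self.base, self.compartment = parse_metabolite_id(self.id)
        if not self.name:
            self.name = self.base

    def element_counts(self) -> dict[str, float] | None:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


_KINDS = ("exchange", "transport", "intracellular", "pseudo")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR.

    ``stoichiometry`` maps metabolite ids to nonzero coefficients; negative
    coefficients are consumed, positive produced.  ``kind`` may be forced to
    ``"pseudo"`` for objective constructs; otherwise it is derived from the
    stoichiometry by :func:`classify_reaction`.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPR = field(default_factory=GPR.empty)
    subsystem: str | None = None
    kind: str | None = None

    def __post_init__(self):
        if not self.name:
            self.name = self.id
        for met_id, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelStructureError(
                    f"reaction {self.id!r} carries zero coefficient for {met_id!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id!r} has inverted bounds "
                f"({self.lower_bound} > {self.upper_bound})"
            )
        if self.kind is not None and self.kind not in _KINDS:
            raise ModelStructureError(f"reaction {self.id!r} has unknown kind {self.kind!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: tuple[float, float]):
        lb, ub = value
        if lb > ub:
            raise ModelStructureError(f"reaction {self.id!r}: inverted bounds ({lb} > {ub})")
        self.lower_bound, self.upper_bound = float(lb), float(ub)


class MetabolicModel:
    """Ordered metabolite/reaction collections plus an objective.

    The stoichiometric matrix is assembled lazily and invalidated on any
    mutation; consumers should treat models as value objects and use
    :meth:`copy` before editing.
    """

    def __init__(
        self,
        metabolites: list[Metabolite] | None = None,
        reactions: list[Reaction] | None = None,
        objective_id: str | None = None,
        name: str = "model",
    ):
        self.name = name
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}
        for m in metabolites or []:
            self.add_metabolite(m)
        for r in reactions or []:
            self.add_reaction(r)
        self.objective_id = objective_id
        if objective_id is not None and objective_id not in self._rxn_index:
            raise ModelStructureError(f"objective {objective_id!r} is not a reaction of the model")

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelStructureError(f"duplicate metabolite id {met.id!r}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                )
        if rxn.kind is None:
            rxn.kind = classify_reaction(rxn, self)
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)

    def remove_reactions(self, ids) -> None:
        drop = set(ids)
        unknown = drop - set(self._rxn_index)
        if unknown:
            raise ModelStructureError(f"cannot remove unknown reactions: {sorted(unknown)}")
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if self.objective_id in drop:
            self.objective_id = None

    # -- access -------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise ModelStructureError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise ModelStructureError(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def S(self) -> sparse.csc_matrix:
        return build_stoichiometric_matrix(self)

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.name}: {self.n_metabolites} metabolites, "
            f"{self.n_reactions} reactions>"
        )

    @classmethod
    def from_reactions(
        cls,
        reactions: list[Reaction],
        objective_id: str | None = None,
        name: str = "model",
        metabolites: list[Metabolite] | None = None,
    ) -> "MetabolicModel":
        """Build a model from reactions, auto-declaring missing metabolites."""
        model = cls(name=name)
        declared = set()
        for met in metabolites or []:
            model.add_metabolite(met)
            declared.add(met.id)
        for rxn in reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in declared:
                    model.add_metabolite(Metabolite(id=met_id))
                    declared.add(met_id)
        for rxn in reactions:
            model.add_reaction(rxn)
        if objective_id is not None:
            model.reaction(objective_id)  # raises if absent
            model.objective_id = objective_id
        return model


def build_stoichiometric_matrix(model: MetabolicModel) -> sparse.csc_matrix:
    """Assemble the sparse m×n stoichiometric matrix of *model*."""
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            if not model.has_metabolite(met_id):
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                )
            rows.append(model._met_index[met_id])
            cols.append(j)
            data.append(float(coef))
    return sparse.csc_matrix(
        (data, (rows, cols)), shape=(model.n_metabolites, model.n_reactions)
    )


def classify_reaction(reaction: Reaction, model: MetabolicModel | None = None) -> str:
    """Classify a reaction as exchange / transport / intracellular.

    Boundary reactions (exactly one metabolite) are exchanges.  A reaction
    moving the same base metabolite between ≥2 compartments is a transport.
    A pre-set ``pseudo`` kind is preserved.
    """
    if not reaction.stoichiometry:
        raise ModelStructureError(f"reaction {reaction.id!r} has empty stoichiometry")
    if reaction.kind == "pseudo":
        return "pseudo"
    if len(reaction.stoichiometry) == 1:
        return "exchange"
    comps_by_base: dict[str, set[str]] = defaultdict(set)
    comps: set[str] = set()
    for met_id in reaction.stoichiometry:
        base, comp = parse_metabolite_id(met_id)
        comps_by_base[base].add(comp)
        comps.add(comp)
    if len(comps) >= 2 and any(len(v) > 1 for v in comps_by_base.values()):
        return "transport"
    return "intracellular"


@dataclass
class ValidationReport:
    """Findings of :func:`validate_model`; empty report means valid."""

    syntax: list[str] = field(default_factory=list)
    imbalances: list[tuple[str, dict[str, float]]] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.syntax or self.imbalances or self.orphans)

    def summary(self) -> str:
        return (
            f"{len(self.syntax)} syntax finding(s), "
            f"{len(self.imbalances)} imbalanced reaction(s), "
            f"{len(self.orphans)} orphan metabolite(s)"
        )


_BALANCE_TOL = 1e-6


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Check id syntax, elemental/charge balance, and orphan metabolites.

    Mass-charge balance is only checked for reactions whose participants all
    carry formulas; exchange and pseudo reactions are exempt.  Orphans are
    metabolites that are produced-only or consumed-only across non-exchange
    reactions and have no exchange reaction of their own.
    """
    report = ValidationReport()

    for met in model.metabolites:
        try:
            parse_metabolite_id(met.id)
        except ModelStructureError as exc:
            report.syntax.append(str(exc))
        if met.formula is not None:
            try:
                parse_formula(met.formula)
            except ModelStructureError as exc:
                report.syntax.append(str(exc))

    produced: dict[str, bool] = defaultdict(bool)
    consumed: dict[str, bool] = defaultdict(bool)
    has_exchange: dict[str, bool] = defaultdict(bool)

    for rxn in model.reactions:
        if not rxn.stoichiometry:
            report.syntax.append(f"reaction {rxn.id!r} has empty stoichiometry")
            continue
        if rxn.lower_bound > rxn.upper_bound:
            report.syntax.append(f"reaction {rxn.id!r} has inverted bounds")

        kind = rxn.kind or classify_reaction(rxn, model)
        if kind == "exchange":
            for met_id in rxn.stoichiometry:
                has_exchange[met_id] = True
            continue
        if kind != "pseudo":
            _check_balance(model, rxn, report)
        for met_id, coef in rxn.stoichiometry.items():
            if coef > 0 or rxn.reversible:
                produced[met_id] = True
            if coef < 0 or rxn.reversible:
                consumed[met_id] = True

    for met in model.metabolites:
        if has_exchange[met.id]:
            continue
        p, c = produced[met.id], consumed[met.id]
        if p != c:  # touched on one side only
            report.orphans.append(met.id)
    return report


def _check_balance(model: MetabolicModel, rxn: Reaction, report: ValidationReport) -> None:
    mets = [model.metabolite(mid) for mid in rxn.stoichiometry]
    if any(m.formula is None for m in mets):
        return  # incompletely annotated: skipped, not failed
    deltas: dict[str, float] = defaultdict(float)
    for met in mets:
        coef = rxn.stoichiometry[met.id]
        for element, count in met.element_counts().items():
            deltas[element] += coef * count
    if all(m.charge is not None for m in mets):
        charge = sum(rxn.stoichiometry[m.id] * m.charge for m in mets)
        if abs(charge) > _BALANCE_TOL:
            deltas["charge"] = charge
    imbalance = {k: v for k, v in deltas.items() if abs(v) > _BALANCE_TOL}
    if imbalance:
        report.imbalances.append((rxn.id, imbalance))
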