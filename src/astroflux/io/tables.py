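"""TSV readers/writers: reaction tables, expression profiles, media, reports.

All report writers emit deterministic output: rows sorted by reaction id and
numbers formatted to six significant digits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from ..errors import TableFormatError
from ..gpr import parse_gpr
from ..model import DEFAULT_BOUND, Reaction
from .formulas import format_reaction_formula, parse_reaction_formula

__all__ = [
    "ExpressionProfile",
    "Medium",
    "read_reaction_table",
    "write_reaction_table",
    "read_expression_table",
    "read_medium",
    "write_flux_report",
    "write_foldchange_report",
]

_FMT = "{:.6g}"


@dataclass
class ExpressionProfile:
    """Mean expression per gene (non-negative, arbitrary units)."""

    values: dict[str, float]

    def __post_init__(self):
        if not self.values:
            raise TableFormatError("expression profile must contain at least one gene")
        for gene, value in self.values.items():
            if value < 0:
                raise TableFormatError(f"negative expression for gene {gene!r}")

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.values.get(gene, default)

    def __contains__(self, gene: str) -> bool:
        return gene in self.values

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Medium:
    """Uptake caps per exchange reaction plus the allowed-output set."""

    uptake: dict[str, float]
    outputs: set[str] = field(default_factory=set)

    def __post_init__(self):
        for rxn_id, cap in self.uptake.items():
            if cap < 0:
                raise TableFormatError(f"negative uptake cap for {rxn_id!r}")


def _read_rows(path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [row for row in reader if row and not row[0].startswith("#")]
    if not rows:
        raise TableFormatError(f"{path}: empty table")
    header = [h.strip().lower() for h in rows[0]]
    return header, rows[1:]


def _col(header: list[str], *names: str) -> int:
    for name in names:
        if name in header:
            return header.index(name)
    raise TableFormatError(f"missing column {names[0]!r} (header: {header})")


def read_reaction_table(path) -> list[Reaction]:
    """Read a reaction TSV (columns: id, formula, optional description/gpr/
    subsystem/lower_bound/upper_bound) into :class:`Reaction` objects.

    Bounds default to (-1000, 1000) for reversible formulas and (0, 1000)
    for irreversible ones.
    """
    header, rows = _read_rows(path)
    i_id = _col(header, "id", "reaction", "rxn")
    i_formula = _col(header, "formula", "formula reaction", "formula_reaction", "equation")
    i_desc = header.index("description") if "description" in header else None
    i_gpr = header.index("gpr") if "gpr" in header else None
    i_sub = header.index("subsystem") if "subsystem" in header else None
    i_lb = header.index("lower_bound") if "lower_bound" in header else None
    i_ub = header.index("upper_bound") if "upper_bound" in header else None

    reactions, seen = [], set()
    for lineno, row in enumerate(rows, start=2):
        rxn_id = row[i_id].strip()
        if not rxn_id:
            raise TableFormatError(f"{path}:{lineno}: empty reaction id")
        if rxn_id in seen:
            raise TableFormatError(f"{path}:{lineno}: duplicate reaction id {rxn_id!r}")
        seen.add(rxn_id)
        stoich, reversible = parse_reaction_formula(row[i_formula])
        lb = float(row[i_lb]) if i_lb is not None and row[i_lb] else (
            -DEFAULT_BOUND if reversible else 0.0
        )
        ub = float(row[i_ub]) if i_ub is not None and row[i_ub] else DEFAULT_BOUND
        reactions.append(
            Reaction(
                id=rxn_id,
                stoichiometry=stoich,
                name=(row[i_desc].strip() if i_desc is not None and len(row) > i_desc else ""),
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(row[i_gpr]) if i_gpr is not None and len(row) > i_gpr else parse_gpr(""),
                subsystem=(row[i_sub].strip() or None) if i_sub is not None and len(row) > i_sub else None,
            )
        )
    return reactions


def write_reaction_table(reactions: list[Reaction], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "formula", "description", "gpr", "subsystem",
                         "lower_bound", "upper_bound"])
        for rxn in reactions:
            writer.writerow([
                rxn.id,
                format_reaction_formula(rxn.stoichiometry, rxn.reversible),
                rxn.name,
                rxn.gpr.to_string(),
                rxn.subsystem or "",
                _FMT.format(rxn.lower_bound),
                _FMT.format(rxn.upper_bound),
            ])


def read_expression_table(path) -> ExpressionProfile:
    """Read a two-column (gene, value) TSV into an :class:`ExpressionProfile`."""
    header, rows = _read_rows(path)
    i_gene = _col(header, "gene", "gene_id", "symbol")
    i_value = _col(header, "value", "expression", "mean", "mean_expression")
    values: dict[str, float] = {}
    for lineno, row in enumerate(rows, start=2):
        gene = row[i_gene].strip()
        if gene in values:
            raise TableFormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
        try:
            value = float(row[i_value])
        except ValueError:
            raise TableFormatError(
                f"{path}:{lineno}: non-numeric expression {row[i_value]!r}"
            ) from None
        if value < 0:
            raise TableFormatError(f"{path}:{lineno}: negative expression for {gene!r}")
        values[gene] = value
    return ExpressionProfile(values)


_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def read_medium(path) -> Medium:
    """Read a medium TSV (exchange_id, max_uptake, is_output)."""
    header, rows = _read_rows(path)
    i_id = _col(header, "exchange_id", "id", "exchange")
    i_cap = _col(header, "max_uptake", "uptake", "cap")
    i_out = header.index("is_output") if "is_output" in header else None
    uptake: dict[str, float] = {}
    outputs: set[str] = set()
    for lineno, row in enumerate(rows, start=2):
        rxn_id = row[i_id].strip()
        cap = float(row[i_cap]) if row[i_cap].strip() else 0.0
        if cap < 0:
            raise TableFormatError(f"{path}:{lineno}: negative uptake cap for {rxn_id!r}")
        if cap > 0:
            if rxn_id in uptake:
                raise TableFormatError(f"{path}:{lineno}: duplicate medium row {rxn_id!r}")
            uptake[rxn_id] = cap
        if i_out is not None and len(row) > i_out:
            flag = row[i_out].strip().lower()
            if flag in _TRUE:
                outputs.add(rxn_id)
            elif flag not in _FALSE:
                raise TableFormatError(f"{path}:{lineno}: bad is_output flag {flag!r}")
    return Medium(uptake=uptake, outputs=outputs)


def write_medium(medium: Medium, path) -> None:
    ids = sorted(set(medium.uptake) | medium.outputs)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["exchange_id", "max_uptake", "is_output"])
        for rxn_id in ids:
            writer.writerow([
                rxn_id,
                _FMT.format(medium.uptake.get(rxn_id, 0.0)),
                "1" if rxn_id in medium.outputs else "0",
            ])


def write_expression_table(profile: ExpressionProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "value"])
        for gene in sorted(profile.values):
            writer.writerow([gene, _FMT.format(profile.values[gene])])


_CLAMP = 1e-9


def write_flux_report(fluxes: dict[str, float], path, clamp: float = _CLAMP) -> None:
    """Write a (reaction_id, flux) TSV; |flux| below *clamp* prints as 0."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["reaction_id", "flux"])
        for rxn_id in sorted(fluxes):
            v = fluxes[rxn_id]
            writer.writerow([rxn_id, _FMT.format(0.0 if abs(v) < clamp else v)])


def write_foldchange_report(records, path) -> None:
    """Write FoldChangeRecord rows (already ordered) to TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["reaction_id", "flux_ref", "flux_alt", "fold_change"])
        for rec in records:
            writer.writerow([
                rec.reaction_id,
                _FMT.format(rec.flux_ref),
                _FMT.format(rec.flux_alt),
                _FMT.format(rec.fold_change),
            ])
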