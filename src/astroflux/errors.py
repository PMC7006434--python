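"""Exception hierarchy shared across the package."""


class AstrofluxError(Exception):
    """Base class for all astroflux errors."""


class ModelStructureError(AstrofluxError):
    """A model violates a structural invariant (unknown metabolite, empty reaction, ...)."""


class FormulaParseError(AstrofluxError):
    """A reaction formula string could not be parsed.

    Carries the character position of the offending token when known.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class TableFormatError(AstrofluxError):
    """A TSV input table is malformed; message names the offending row."""


class SolverError(AstrofluxError):
    """The LP backend failed in a way that cannot be expressed as a status."""


class InfeasibleModelError(AstrofluxError):
    """An operation requiring a feasible model was given an infeasible one."""


class DegenerateProfileError(AstrofluxError):
    """All GPR scores are zero: expression profile cannot scale bounds."""


class UndefinedIC50Error(AstrofluxError):
    """A robustness curve never falls to half of its maximum."""


class ScenarioError(AstrofluxError):
    """Scenario construction failed (missing control reaction, bad spec)."""
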