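"""Synthetic toy astrocyte network with known ground truth.

The network couples every export objective to a shared, finitely regenerated
mitochondrial cofactor pool.  Forcing palmitate uptake consumes the pool
through β-oxidation, so each objective's optimum declines linearly from its
unconstrained maximum to zero at a configurable uptake ``inhibition_u0`` —
giving every robustness curve the closed form z(u) = z0·(1 − u/u0) and an
IC50 of exactly u0/2.

Stoichiometric yields mirror the classical lumped conversions
1 glucose → 2 lactate (fermentative) and 1 glucose → 36 ATP (oxidative).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np

from .errors import AstrofluxError
from .fba import solve_fba
from .gpr import parse_gpr
from .io.tables import ExpressionProfile, Medium, read_reaction_table
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyParams",
    "generate_toy_astrocyte",
    "generate_expression_profile",
    "tibolone_reactions",
    "estradiol_stub_reactions",
    "toy_medium",
    "disable_oxidative_route",
    "TOY_OBJECTIVES",
    "BIOMASS_ID",
    "PALMITATE_EXCHANGE",
    "OXIDATIVE_ROUTE_ID",
]

#: Table-style export objectives of the toy, in a fixed order:
#: glutamine, D-serine, lactate, ATP demand, reduced glutathione.
TOY_OBJECTIVES = [
    "EX_gln_L(e)",
    "EX_ser_D(e)",
    "EX_lac_L(e)",
    "DM_atp",
    "EX_gthrd(e)",
]
BIOMASS_ID = "BIOMASS"
PALMITATE_EXCHANGE = "EX_hdca(e)"
OXIDATIVE_ROUTE_ID = "OXPHOS"

#: Regeneration capacity of the shared cofactor pool (mmol·gDW⁻¹·h⁻¹).
#: 36 keeps every default cofactor coefficient exactly representable in the
#: 15 significant digits SBML serialization carries.
POOL_CAPACITY = 36.0

# Fixed uptake caps for the non-parametric substrates.
_CAPS = {
    "glu_L": 1.0,
    "gly": 1.0,
    "cys_L": 1.0,
    "ala_L": 1.0,
    "nh3": 10.0,
    "fald": 10.0,
    "o2": 100.0,
}

_BIOMASS_COF = 0.2 * POOL_CAPACITY  # cofactor per unit biomass


@dataclass
class ToyParams:
    """Knobs of the toy generator; defaults reproduce the reference yields."""

    glucose_cap: float = 1.0
    palmitate_cap: float = 1.0
    atp_yield_ox: int = 36
    lactate_yield: int = 2
    inhibition_u0: float = 0.5
    seed: int = 7
    include_tibolone: bool = False
    include_estradiol_stub: bool = False

    def __post_init__(self):
        if self.atp_yield_ox <= 0 or self.lactate_yield <= 0:
            raise AstrofluxError("yields must be positive integers")
        if not (0.0 < self.inhibition_u0 <= 1.0):
            raise AstrofluxError("inhibition_u0 must lie in (0, 1]")
        if self.glucose_cap <= 0 or self.palmitate_cap <= 0:
            raise AstrofluxError("uptake caps must be positive")


def _metabolites(params: ToyParams) -> list[Metabolite]:
    # Lumped toy chemistry: `atp`/`pi` are phosphate tokens (element P) and
    # the cofactor pair uses the fictional element X, so every non-exempt
    # reaction balances exactly.  The lumped pyruvate formula C3H6O3 only
    # balances glycolysis for the default yield of 2; for nonstandard yields
    # the glycolytic species are left unannotated (skipped by validation).
    standard = params.lactate_yield == 2
    defs = [
        ("glc_D[e]", "D-glucose", "C6H12O6"),
        ("glc_D[c]", "D-glucose", "C6H12O6"),
        ("pyr[c]", "pyruvate (lumped)", "C3H6O3" if standard else None),
        ("lac_L[c]", "L-lactate", "C3H6O3"),
        ("lac_L[e]", "L-lactate", "C3H6O3"),
        ("atp[c]", "ATP token", "P"),
        ("pi[c]", "phosphate token", "P"),
        ("glu_L[e]", "L-glutamate", "C5H9NO4"),
        ("glu_L[c]", "L-glutamate", "C5H9NO4"),
        ("gln_L[e]", "L-glutamine", "C5H10N2O3"),
        ("nh3[e]", "ammonia", "H3N"),
        ("gly[e]", "glycine", "C2H5NO2"),
        ("gly[c]", "glycine", "C2H5NO2"),
        ("ser_D[e]", "D-serine", "C3H7NO3"),
        ("fald[e]", "formaldehyde", "CH2O"),
        ("cys_L[e]", "L-cysteine", "C3H7NO2S"),
        ("gthrd[e]", "reduced glutathione", "C10H17N3O6S"),
        ("h2o[e]", "water", "H2O"),
        ("o2[e]", "oxygen", "O2"),
        ("co2[e]", "carbon dioxide", "CO2"),
        ("hdca[e]", "palmitate", "C16H32O2"),
        ("hdca[c]", "palmitate", "C16H32O2"),
        ("ala_L[e]", "L-alanine", "C3H7NO2"),
        ("ala_L[c]", "L-alanine", "C3H7NO2"),
        ("cof[m]", "free mitochondrial cofactor", "X"),
        ("cofu[m]", "spent mitochondrial cofactor", "X"),
    ]
    if not standard:
        defs = [(i, n, (None if i.startswith(("glc_D", "pyr")) else f)) for i, n, f in defs]
    return [Metabolite(id=i, name=n, formula=f, charge=0 if f else None) for i, n, f in defs]


def generate_toy_astrocyte(params: ToyParams | None = None) -> MetabolicModel:
    """Build the toy astrocyte model (~32 reactions, 4 compartments used)."""
    params = params or ToyParams()
    L = float(params.lactate_yield)
    ox_per_pyr = (params.atp_yield_ox - 2.0) / L  # oxidative ATP per pyruvate
    if ox_per_pyr <= 0:
        raise AstrofluxError("atp_yield_ox must exceed the glycolytic yield of 2")
    K = POOL_CAPACITY
    # Cofactor cost per unit of each objective, sized so the pool alone
    # limits the objective to its substrate-capped maximum at zero palmitate.
    a_gln = K / _CAPS["glu_L"]
    a_ser = K / _CAPS["gly"]
    a_lac = K / (L * params.glucose_cap)
    a_atp = K / (params.atp_yield_ox * params.glucose_cap)
    a_gth = K / min(_CAPS["cys_L"], _CAPS["glu_L"], _CAPS["gly"])
    b_pal = K / params.inhibition_u0  # cofactor per unit palmitate oxidized

    mets = _metabolites(params)
    B = DEFAULT_BOUND

    def ex(met_id, cap=0.0, name=""):
        base = met_id.split("[")[0]
        return Reaction(
            id=f"EX_{base}(e)",
            stoichiometry={met_id: -1.0},
            name=name or f"{base} exchange",
            lower_bound=-cap,
            upper_bound=B,
            subsystem="Exchange",
        )

    def rxn(rid, stoich, name="", gpr="", subsystem=None, lb=0.0, ub=B, kind=None):
        return Reaction(
            id=rid, stoichiometry=stoich, name=name, lower_bound=lb, upper_bound=ub,
            gpr=parse_gpr(gpr), subsystem=subsystem, kind=kind,
        )

    reactions = [
        # exchanges (uptake caps follow the toy medium)
        ex("glc_D[e]", params.glucose_cap),
        ex("glu_L[e]", _CAPS["glu_L"]),
        ex("gly[e]", _CAPS["gly"]),
        ex("cys_L[e]", _CAPS["cys_L"]),
        ex("ala_L[e]", _CAPS["ala_L"]),
        ex("nh3[e]", _CAPS["nh3"]),
        ex("fald[e]", _CAPS["fald"]),
        ex("o2[e]", _CAPS["o2"]),
        ex("hdca[e]", params.palmitate_cap, name="palmitate exchange"),
        ex("lac_L[e]"),
        ex("gln_L[e]"),
        ex("ser_D[e]"),
        ex("gthrd[e]"),
        ex("co2[e]"),
        ex("h2o[e]"),
        # transports
        rxn("GLCt", {"glc_D[e]": -1, "glc_D[c]": 1}, "glucose transport",
            "SLC2A1", "Transport"),
        rxn("GLUt", {"glu_L[e]": -1, "glu_L[c]": 1}, "glutamate transport (GLAST)",
            "SLC1A3 or SLC1A2", "Transport"),
        rxn("GLYt", {"gly[e]": -1, "gly[c]": 1}, "glycine transport",
            "SLC6A9", "Transport"),
        rxn("ALAt", {"ala_L[e]": -1, "ala_L[c]": 1}, "alanine transport",
            "SLC38A1", "Transport"),
        rxn("HDCAt", {"hdca[e]": -1, "hdca[c]": 1}, "palmitate transport",
            "SLC27A1", "Transport"),
        rxn("LACt", {"lac_L[c]": -1, "cof[m]": -a_lac, "lac_L[e]": 1, "cofu[m]": a_lac},
            "lactate release", "SLC16A1", "Transport"),
        # core routes
        rxn("GLYC", {"glc_D[c]": -1, "pi[c]": -2, "pyr[c]": L, "atp[c]": 2},
            "lumped glycolysis", "HK1 and PFKL and PKM", "Glycolysis"),
        rxn("LDH", {"pyr[c]": -1, "lac_L[c]": 1}, "lactate dehydrogenase",
            "LDHA or LDHB", "Glycolysis"),
        rxn("OXPHOS",
            {"pyr[c]": -1, "o2[e]": -3, "pi[c]": -ox_per_pyr,
             "co2[e]": 3, "h2o[e]": 3, "atp[c]": ox_per_pyr},
            "lumped oxidative route", "NDUFS1 and SDHA and COX4I1",
            "Oxidative phosphorylation"),
        rxn("GLNS", {"glu_L[c]": -1, "nh3[e]": -1, "cof[m]": -a_gln,
                     "gln_L[e]": 1, "h2o[e]": 1, "cofu[m]": a_gln},
            "glutamine synthetase", "GLUL", "Glutamate metabolism"),
        rxn("SHMT", {"gly[c]": -1, "fald[e]": -1, "cof[m]": -a_ser,
                     "ser_D[e]": 1, "cofu[m]": a_ser},
            "glycine to D-serine conversion", "SHMT1 or SHMT2",
            "Glycine and serine metabolism"),
        rxn("GSHS", {"cys_L[e]": -1, "glu_L[c]": -1, "gly[c]": -1, "cof[m]": -a_gth,
                     "gthrd[e]": 1, "h2o[e]": 2, "cofu[m]": a_gth},
            "glutathione synthesis and release", "GCLC and GSS",
            "Glutathione metabolism"),
        rxn("ATPM", {"atp[c]": -1, "pi[c]": 1}, "non-growth ATP maintenance",
            subsystem="Energy maintenance"),
        rxn("DM_atp", {"atp[c]": -1, "cof[m]": -a_atp, "pi[c]": 1, "cofu[m]": a_atp},
            "ATP demand", subsystem="Energy maintenance"),
        rxn("BOX", {"hdca[c]": -1, "o2[e]": -23, "cof[m]": -b_pal,
                    "co2[e]": 16, "h2o[e]": 16, "cofu[m]": b_pal},
            "palmitate beta-oxidation", "CPT1A and ACADVL and HADHA",
            "Fatty acid degradation"),
        rxn("COFR", {"cofu[m]": -1, "cof[m]": 1}, "cofactor regeneration",
            subsystem="Cofactor regeneration", ub=K),
        rxn("BIOMASS", {"ala_L[c]": -1, "cof[m]": -_BIOMASS_COF, "cofu[m]": _BIOMASS_COF},
            "biomass pseudo-reaction", subsystem="Biomass", kind="pseudo"),
    ]

    model = MetabolicModel(metabolites=mets, reactions=reactions,
                           objective_id=BIOMASS_ID, name="toy_astrocyte")

    if params.include_tibolone:
        _append(model, tibolone_reactions())
    if params.include_estradiol_stub:
        _append(model, estradiol_stub_reactions())

    healthy = solve_fba(model, BIOMASS_ID, "max")
    if not healthy.optimal or healthy.objective_value <= 0:
        raise AstrofluxError(
            f"parameter combination yields an infeasible healthy model "
            f"(biomass status {healthy.status})"
        )
    return model


def _append(model: MetabolicModel, reactions: list[Reaction]) -> None:
    for rxn in reactions:
        for met_id in rxn.stoichiometry:
            if not model.has_metabolite(met_id):
                model.add_metabolite(Metabolite(id=met_id))
        model.add_reaction(rxn)


def tibolone_reactions() -> list[Reaction]:
    """The ten packaged tibolone reactions (T1–T10), parsed from the data file."""
    path = resources.files("astroflux.data") / "tibolone_reactions.tsv"
    return read_reaction_table(path)


#: Cofactor regenerated per estradiol consumed by the relief reaction.
RELIEF_YIELD = 4.0 * POOL_CAPACITY


def estradiol_stub_reactions() -> list[Reaction]:
    """Configurable stand-in for the estradiol-derived reaction set.

    Five placeholder reactions: an estradiol-dependent relief step that
    regenerates the shared cofactor pool (the measurable treatment effect),
    its byproduct sink, and an inert three-step chain.
    """
    def rxn(rid, stoich, name, gpr=""):
        return Reaction(id=rid, stoichiometry=stoich, name=name,
                        lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                        gpr=parse_gpr(gpr), subsystem="Steroid metabolism")

    return [
        rxn("ES1", {"estradiol[c]": -1.0, "cofu[m]": -RELIEF_YIELD,
                    "cof[m]": RELIEF_YIELD, "e2deriv[c]": 1.0},
            "estradiol-dependent cofactor relief", "ABCD3"),
        rxn("ES2", {"e2deriv[c]": -1.0}, "estradiol derivative sink"),
        rxn("ES3", {"estradiol[c]": -1.0, "e2x[c]": 1.0}, "estradiol derivatization"),
        rxn("ES4", {"e2x[c]": -1.0, "e2s[c]": 1.0}, "derivative sulfation"),
        rxn("ES5", {"e2s[c]": -1.0}, "sulfated derivative sink"),
    ]


def toy_medium(params: ToyParams | None = None) -> Medium:
    """Medium mirroring the toy's uptake caps and allowed outputs."""
    params = params or ToyParams()
    uptake = {
        "EX_glc_D(e)": params.glucose_cap,
        "EX_glu_L(e)": _CAPS["glu_L"],
        "EX_gly(e)": _CAPS["gly"],
        "EX_cys_L(e)": _CAPS["cys_L"],
        "EX_ala_L(e)": _CAPS["ala_L"],
        "EX_nh3(e)": _CAPS["nh3"],
        "EX_fald(e)": _CAPS["fald"],
        "EX_o2(e)": _CAPS["o2"],
        "EX_hdca(e)": params.palmitate_cap,
    }
    outputs = {"EX_lac_L(e)", "EX_gln_L(e)", "EX_ser_D(e)", "EX_gthrd(e)",
               "EX_co2(e)", "EX_h2o(e)"}
    return Medium(uptake=uptake, outputs=outputs)


def disable_oxidative_route(model: MetabolicModel) -> MetabolicModel:
    """Copy of the toy with the oxidative route shut (bounds 0, 0)."""
    closed = model.copy()
    closed.reaction(OXIDATIVE_ROUTE_ID).bounds = (0.0, 0.0)
    return closed


def generate_expression_profile(
    model: MetabolicModel,
    seed: int,
    mu: float = 2.0,
    sigma: float = 0.5,
) -> ExpressionProfile:
    """Log-normal mean expression for every distinct gene in the model."""
    genes = sorted({g for r in model.reactions for g in r.gpr.genes()})
    if not genes:
        raise AstrofluxError("model has no GPR-bearing reactions")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=mu, sigma=sigma, size=len(genes))
    return ExpressionProfile(dict(zip(genes, (float(d) for d in draws))))
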