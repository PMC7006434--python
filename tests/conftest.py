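import pytest

from astroflux import synth
from astroflux.constraints import apply_medium
from astroflux.gpr import GPR
from astroflux.model import MetabolicModel, Metabolite, Reaction


@pytest.fixture(scope="session")
def toy_params():
    return synth.ToyParams()


@pytest.fixture(scope="session")
def toy_model(toy_params):
    return synth.generate_toy_astrocyte(toy_params)


@pytest.fixture(scope="session")
def healthy_model(toy_model, toy_params):
    return apply_medium(toy_model, synth.toy_medium(toy_params))


def make_chain_model(cap=5.0):
    """E_in (uptake <= cap) -> A -> B -> E_out, all irreversible."""
    mets = [Metabolite(id="A[c]"), Metabolite(id="B[c]")]
    rxns = [
        Reaction(id="E_in", stoichiometry={"A[c]": -1.0}, lower_bound=-cap, upper_bound=0.0),
        Reaction(id="STEP", stoichiometry={"A[c]": -1.0, "B[c]": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="E_out", stoichiometry={"B[c]": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, objective_id="E_out")


def make_parallel_model():
    """Two equivalent routes A->B: direct, and via intermediate (2 steps)."""
    mets = [Metabolite(id="A[c]"), Metabolite(id="B[c]"), Metabolite(id="I[c]")]
    rxns = [
        Reaction(id="E_in", stoichiometry={"A[c]": -1.0}, lower_bound=-1.0, upper_bound=0.0),
        Reaction(id="DIRECT", stoichiometry={"A[c]": -1.0, "B[c]": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="LONG1", stoichiometry={"A[c]": -1.0, "I[c]": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="LONG2", stoichiometry={"I[c]": -1.0, "B[c]": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="E_out", stoichiometry={"B[c]": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, objective_id="E_out")


def make_cycle_model():
    """A->B->C->A internal cycle beside a through-path A->out."""
    mets = [Metabolite(id="A[c]"), Metabolite(id="B[c]"), Metabolite(id="C[c]")]
    rxns = [
        Reaction(id="E_in", stoichiometry={"A[c]": -1.0}, lower_bound=-1.0, upper_bound=0.0),
        Reaction(id="AB", stoichiometry={"A[c]": -1.0, "B[c]": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="BC", stoichiometry={"B[c]": -1.0, "C[c]": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="CA", stoichiometry={"C[c]": -1.0, "A[c]": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="E_out", stoichiometry={"A[c]": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, objective_id="E_out")


def model_to_dicts(model):
    """Plain-dict view of a model for the test-side oracles."""
    return (
        [
            {"id": r.id, "stoichiometry": dict(r.stoichiometry),
             "lb": r.lower_bound, "ub": r.upper_bound}
            for r in model.reactions
        ],
        model.metabolite_ids(),
    )


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def parallel_model():
    return make_parallel_model()


@pytest.fixture
def cycle_model():
    return make_cycle_model()


def balanced_pair_model():
    """Glucose-to-lactate style split with formulas attached (balanced)."""
    mets = [
        Metabolite(id="hex[c]", formula="C6H12O6", charge=0),
        Metabolite(id="tri[c]", formula="C3H6O3", charge=0),
    ]
    rxns = [
        Reaction(id="E_hex", stoichiometry={"hex[c]": -1.0}, lower_bound=-5.0,
                 upper_bound=0.0),
        Reaction(id="SPLIT", stoichiometry={"hex[c]": -1.0, "tri[c]": 2.0},
                 lower_bound=0.0, upper_bound=1000.0, gpr=GPR.leaf("ENZ1")),
        Reaction(id="E_tri", stoichiometry={"tri[c]": -1.0}, lower_bound=0.0,
                 upper_bound=1000.0),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, objective_id="E_tri")
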