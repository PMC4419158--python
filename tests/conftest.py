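import numpy as np
import pytest

from exoflux import contextualize, exoconstraints as exo, netcore, synthdata


def build_model(reactions, objective, compartments=None, model_id="fixture"):
    """Compact model builder: reactions as (id, stoich, lb, ub, gpr)."""
    mets = {}
    rxns = []
    for rid, stoich, lb, ub, gpr in reactions:
        for met in stoich:
            mets.setdefault(met, {"id": met, "name": met,
                                  "compartment": met.rsplit("_", 1)[-1]})
        rxns.append({"id": rid, "stoichiometry": stoich,
                     "lower_bound": lb, "upper_bound": ub, "gpr": gpr})
    return netcore.model_from_dict({
        "id": model_id,
        "compartments": compartments or {"c": "cytosol", "e": "extra"},
        "metabolites": list(mets.values()),
        "reactions": rxns,
        "objective": objective,
    })


def chain_model(uptake_lb=-10.0, gpr_mid="", model_id="chain"):
    """EX_A (lb uptake_lb) -> transport -> conversion -> biomass drain."""
    return build_model([
        ("EX_a_e", {"a_e": -1}, uptake_lb, 0.0, ""),
        ("T_a", {"a_e": -1, "a_c": 1}, 0.0, 500.0, ""),
        ("CONV", {"a_c": -1, "b_c": 1}, 0.0, 500.0, gpr_mid),
        ("BIO", {"b_c": -1}, 0.0, 500.0, ""),
    ], objective="BIO", model_id=model_id)


def random_toy(rng: np.random.Generator):
    """A random small network with randomized supply bounds, always feasible."""
    spec = synthdata.ToySpec(
        n_glycolysis_steps=int(rng.integers(1, 6)),
        n_cycle_steps=int(rng.integers(2, 5)),
        n_etc_steps=int(rng.integers(1, 4)),
        n_isozyme_pairs=int(rng.integers(0, 3)),
        n_dead_ends=int(rng.integers(0, 4)),
    )
    model = synthdata.make_toy_network(spec)
    model.reactions.EX_glc_e.lower_bound = float(rng.uniform(-30.0, -5.0))
    model.reactions.EX_o2_e.lower_bound = float(rng.uniform(-5.0, -1.0))
    model.reactions.ATPM.upper_bound = float(rng.uniform(10.0, 100.0))
    bio = model.reactions.BIOMASS
    max_growth = netcore.fba(model).objective_value
    bio.bounds = (0.5 * max_growth, 0.9 * max_growth)
    return model


@pytest.fixture(scope="session")
def toy_model():
    return synthdata.make_toy_network()


@pytest.fixture(scope="session")
def params_A():
    return exo.CultureParams()


@pytest.fixture(scope="session")
def params_B():
    return exo.CultureParams(growth_rate_per_h=0.032)


@pytest.fixture(scope="session")
def truth():
    return synthdata.SyntheticTruth()


@pytest.fixture(scope="session")
def measurements(toy_model, truth, params_A):
    frame = synthdata.simulate_exo_profiles(toy_model, truth, params_A, seed=7)
    return [exo.ExoMeasurement(r.metabolite_id, r.condition, r.signal_t0,
                               r.signal_t1, r.detection_limit_mM,
                               r.medium_conc_mM)
            for r in frame.itertuples()]


@pytest.fixture(scope="session")
def no_calls():
    return contextualize.ExpressionCalls({})
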