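import itertools

import numpy as np
import pytest

from repertoire import synth
from repertoire.fba_core import (
    GapFillError,
    find_futile_cycles,
    flux_variability,
    gap_fill,
    producible_byproducts,
    scan_auxotrophies,
    solve_fba,
    utilizable_carbon_sources,
)
from repertoire.model_io import Medium, MetabolicModel, Metabolite, Reaction


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("yield_,uptake", [(0.5, 10.0), (0.0, 10.0), (0.9, 3.0),
                                           (0.25, 16.0)])
def test_fba_chain_closed_form(yield_, uptake):
    model, medium = synth.make_chain_model(yield_=yield_, uptake=uptake)
    sol = solve_fba(model, medium)
    assert sol.optimal
    assert sol.objective == pytest.approx(yield_ * uptake, abs=1e-6)


def test_fba_no_carbon_gives_zero(chain):
    model, _ = chain
    sol = solve_fba(model, Medium(name="empty", uptake_limits={}))
    assert sol.objective == pytest.approx(0.0, abs=1e-9)


def test_fba_two_chains_optimum_is_sum():
    model, medium = synth.make_multichain_model({"a": (0.5, 10.0),
                                                 "b": (0.3, 4.0)})
    assert solve_fba(model, medium).objective == pytest.approx(6.2, abs=1e-6)


def test_fba_contradictory_bounds_infeasible(chain):
    model, medium = chain
    # force uptake through a transporter that medium closes
    model.reaction_map["T_glc"].lower_bound = 5.0
    sol = solve_fba(model, Medium(name="empty", uptake_limits={}))
    assert sol.status == "infeasible"


def test_fba_steady_state_residual(chain):
    model, medium = chain
    sol = solve_fba(model, medium)
    from repertoire.fba_core import stoichiometric_matrix
    S, _, rxn_ids = stoichiometric_matrix(model.metabolites, model.reactions)
    # medium changes bounds, not S; the flux vector is in rxn order
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    assert np.abs(S @ v).max() < 1e-6


def test_fba_matches_cobra_oracle(fermenter):
    """Independent cross-check against the COBRA reference implementation."""
    cobra = pytest.importorskip("cobra")
    model, medium = fermenter
    cm = cobra.Model("oracle")
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites}
    from repertoire.model_io import apply_medium
    bounded = apply_medium(model, medium)
    for r in bounded.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound,
                            upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
    cm.objective = "biomass"
    expected = cm.optimize().objective_value
    assert solve_fba(model, medium).objective == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def test_fva_chain_hand_lp(chain):
    model, medium = chain
    (res,) = flux_variability(model, medium, ["EX_glc_e"], objective_fraction=1.0)
    assert res.min_flux == pytest.approx(-10.0, abs=1e-6)
    assert res.max_flux == pytest.approx(-10.0, abs=1e-6)
    (free,) = flux_variability(model, medium, ["EX_glc_e"], objective_fraction=0.0)
    assert free.min_flux == pytest.approx(-10.0, abs=1e-6)
    assert free.max_flux == pytest.approx(0.0, abs=1e-6)


def test_fva_dead_end_reaction_blocked(rng):
    # regenerate toys until one has the dead-end branch
    for _ in range(20):
        model, medium = synth.make_random_toy_model(rng)
        if "R_dead" in model.reaction_map:
            (res,) = flux_variability(model, medium, ["R_dead"],
                                      objective_fraction=0.0)
            assert res.min_flux == pytest.approx(0.0, abs=1e-9)
            assert res.max_flux == pytest.approx(0.0, abs=1e-9)
            return
    pytest.fail("no dead-end toy generated")


def test_fva_contains_fba_flux_and_monotonicity(rng):
    """FVA intervals contain the FBA flux; relaxing a bound or adding a
    reaction never decreases the optimum (50 random toy models)."""
    for i in range(50):
        model, medium = synth.make_random_toy_model(rng, model_id=f"toy{i}")
        sol = solve_fba(model, medium)
        assert sol.optimal
        res = flux_variability(model, medium, objective_fraction=1.0)
        for r in res:
            assert r.min_flux <= r.max_flux + 1e-9
            assert r.min_flux - 1e-6 <= sol.fluxes[r.reaction_id] <= r.max_flux + 1e-6
        # relax the uptake bound
        relaxed = Medium(name="relaxed", uptake_limits={
            m: v * 2 for m, v in medium.uptake_limits.items()})
        assert solve_fba(model, relaxed).objective >= sol.objective - 1e-8
        # add a parallel uptake route
        grown = model.copy()
        grown.reactions.append(Reaction(
            id="T_extra", stoichiometry={"s_e": -1.0, "m0_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0))
        assert solve_fba(grown, medium).objective >= sol.objective - 1e-8


# ---------------------------------------------------------------------------
# Utilizability / byproducts
# ---------------------------------------------------------------------------

def test_utilizable_carbon_sources(chain, caplog):
    model, _ = chain
    base = Medium(name="none", uptake_limits={})
    out = utilizable_carbon_sources(model, base, ["glc_e"])
    assert out == {"glc_e": True}
    # no transporter -> minimum is 0 -> not utilizable
    crippled = model.copy()
    crippled.reactions = [r for r in crippled.reactions if r.id != "T_glc"]
    assert not utilizable_carbon_sources(crippled, base, ["glc_e"])["glc_e"]
    with caplog.at_level("WARNING", logger="repertoire"):
        out = utilizable_carbon_sources(model, base, ["nope_e"])
    assert out["nope_e"] is False and "nope_e" in caplog.text


def test_producible_byproducts(fermenter):
    model, medium = fermenter
    out = producible_byproducts(model, medium, ["ac_e", "glc_e"])
    assert out["ac_e"] is True     # fermentation route exports acetate
    assert out["glc_e"] is False   # sole carbon source cannot be net-exported


def test_no_secretion_route_not_producible(chain):
    model, medium = chain
    assert producible_byproducts(model, medium, ["glc_e"]) == {"glc_e": False}


# ---------------------------------------------------------------------------
# Auxotrophy scan
# ---------------------------------------------------------------------------

def _biosynth_model():
    """glc -> precursor -> component X, plus exchange for X."""
    return MetabolicModel(
        id="biosynth",
        metabolites=[
            Metabolite(id="glc_e", compartment="e"),
            Metabolite(id="glc_c", compartment="c"),
            Metabolite(id="x_c", compartment="c"),
            Metabolite(id="x_e", compartment="e"),
        ],
        reactions=[
            Reaction(id="EX_glc_e", stoichiometry={"glc_e": -1.0},
                     lower_bound=-10, upper_bound=1000, is_exchange=True),
            Reaction(id="EX_x_e", stoichiometry={"x_e": -1.0},
                     lower_bound=0, upper_bound=1000, is_exchange=True),
            Reaction(id="T_glc", stoichiometry={"glc_e": -1, "glc_c": 1},
                     lower_bound=0, upper_bound=1000),
            Reaction(id="T_x", stoichiometry={"x_e": -1, "x_c": 1},
                     lower_bound=0, upper_bound=1000),
            Reaction(id="SYNTH_x", stoichiometry={"glc_c": -1, "x_c": 1},
                     lower_bound=0, upper_bound=1000),
            Reaction(id="biomass", stoichiometry={"glc_c": -1, "x_c": -0.1},
                     lower_bound=0, upper_bound=1000, is_biomass=True),
        ],
        biomass_id="biomass",
    ).validate()


def test_auxotrophy_scan_detects_knockout():
    model = _biosynth_model()
    medium = Medium(name="min", uptake_limits={"glc_e": 10.0})
    assert scan_auxotrophies(model, medium, ["x_c"]) == []
    knockout = model.copy()
    knockout.reactions = [r for r in knockout.reactions if r.id != "SYNTH_x"]
    assert scan_auxotrophies(knockout, medium, ["x_c"]) == ["x_c"]
    assert scan_auxotrophies(knockout, medium, []) == []


# ---------------------------------------------------------------------------
# Futile cycles
# ---------------------------------------------------------------------------

def test_futile_cycle_two_reaction_loop(chain):
    model, _ = chain
    assert find_futile_cycles(model) == []  # acyclic chain
    looped = model.copy()
    looped.reactions += [
        Reaction(id="LOOP_fwd", stoichiometry={"glc_c": -1.0, "glc_e": 1.0},
                 lower_bound=0, upper_bound=100),
        Reaction(id="LOOP_back", stoichiometry={"glc_e": -1.0, "glc_c": 1.0},
                 lower_bound=0, upper_bound=100),
    ]
    flagged = find_futile_cycles(looped)
    # LOOP_back also cycles with the forward transporter, so all three can
    # carry flux with exchanges closed; biomass cannot
    assert {"LOOP_fwd", "LOOP_back"} <= set(flagged)
    assert "biomass" not in flagged


def test_single_reversible_reaction_is_not_a_cycle(chain):
    model, _ = chain
    model.reaction_map["T_glc"].lower_bound = -1000.0  # reversible alone
    assert find_futile_cycles(model) == []


def test_closed_exchanges_zero_biomass(rng):
    for i in range(10):
        model, _ = synth.make_random_toy_model(rng, model_id=f"closed{i}")
        sol = solve_fba(model, Medium(name="none", uptake_limits={}))
        assert sol.objective == pytest.approx(0.0, abs=1e-8)


# ---------------------------------------------------------------------------
# Gap-filling
# ---------------------------------------------------------------------------

def _enumeration_oracle(model, pool, medium, min_growth):
    """Smallest pool subsets achieving growth, by exhaustive enumeration."""
    from repertoire.fba_core import _growth_with

    for size in range(len(pool) + 1):
        hits = [
            set(sub) for sub in itertools.combinations([r.id for r in pool], size)
            if _growth_with(model, pool, list(sub), medium) >= min_growth - 1e-6
        ]
        if hits:
            return size, hits
    return None, []


@pytest.mark.parametrize("n_decoys", [3, 7, 11])
def test_gap_fill_matches_exhaustive_enumeration(n_decoys):
    model, pool, medium, needed = synth.make_gapfill_fixture(n_decoys=n_decoys)
    res = gap_fill(model, pool, medium, min_growth=1.0)
    assert res.added_reaction_ids == [needed]
    assert res.achieved_growth >= 1.0 - 1e-6
    size, hits = _enumeration_oracle(model, pool, medium, 1.0)
    assert size == len(res.added_reaction_ids)
    assert set(res.added_reaction_ids) in hits


def test_gap_fill_already_growing_returns_empty(chain):
    model, medium = chain
    pool = [Reaction(id="POOL_x", stoichiometry={"glc_c": -1.0},
                     lower_bound=0, upper_bound=10)]
    res = gap_fill(model, pool, medium, min_growth=1.0)
    assert res.added_reaction_ids == []


def test_gap_fill_unfillable_raises():
    model, pool, medium, needed = synth.make_gapfill_fixture(n_decoys=2)
    useless = [r for r in pool if r.id != needed]
    with pytest.raises(GapFillError, match="unfillable"):
        gap_fill(model, useless, medium, min_growth=1.0)


def test_gap_fill_rejects_id_collision(chain):
    model, medium = chain
    pool = [Reaction(id="T_glc", stoichiometry={"glc_e": -1, "glc_c": 1},
                     lower_bound=0, upper_bound=1000)]
    with pytest.raises(ValueError, match="collide"):
        gap_fill(model, pool, medium, min_growth=0.1)
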