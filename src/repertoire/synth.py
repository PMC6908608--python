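"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments (including the seed) and
returns the planted ground truth alongside the data, so every analysis stage
can be tested without any external download.  Toy metabolic models are kept
tiny (<= 25 reactions) so that LP oracles and exhaustive gap-fill
enumeration remain trivial.

The media fixtures mirror the structure of an isolation-grade rich medium
(several carbon sources in finite supply plus a vitamin) versus a
single-carbon minimal medium with trace requirements, without reproducing
any real composition.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .dfba import EnzymeSpecies
from .model_io import (
    HitRecord,
    Medium,
    MetabolicModel,
    Metabolite,
    PathwayDefinition,
    Reaction,
)

BASES = "ACGT"

#: carbon atoms per toy metabolite (used by mass-balance checks)
CARBON_ATOMS = {
    "suc_e": 12, "glc_e": 6, "fru_e": 6, "glc_c": 6, "fru_c": 6,
    "ac_e": 2, "ac_c": 2,
}
#: carbon per unit biomass of the invertase-scenario members (1 glc + 1 fru)
BIOMASS_CARBON = 12


# ---------------------------------------------------------------------------
# Toy models with closed-form FBA optima
# ---------------------------------------------------------------------------

def make_chain_model(
    yield_: float = 0.5,
    uptake: float = 10.0,
    carbon_id: str = "glc",
    model_id: str | None = None,
) -> tuple[MetabolicModel, Medium]:
    """Linear uptake -> transport -> biomass chain.

    The FBA optimum is analytically ``yield_ * uptake`` (the biomass
    reaction consumes ``1/yield_`` units of cytosolic carbon per unit
    growth).
    """
    e, c = f"{carbon_id}_e", f"{carbon_id}_c"
    if yield_ > 0:
        biomass = Reaction(id="biomass", stoichiometry={c: -1.0 / yield_},
                           lower_bound=0.0, upper_bound=1000.0, is_biomass=True)
    else:
        biomass = Reaction(id="biomass", stoichiometry={c: -1.0},
                           lower_bound=0.0, upper_bound=0.0, is_biomass=True)
    model = MetabolicModel(
        id=model_id or f"chain_{carbon_id}",
        metabolites=[Metabolite(id=e, compartment="e"),
                     Metabolite(id=c, compartment="c")],
        reactions=[
            Reaction(id=f"EX_{e}", stoichiometry={e: -1.0},
                     lower_bound=-uptake, upper_bound=1000.0, is_exchange=True),
            Reaction(id=f"T_{carbon_id}", stoichiometry={e: -1.0, c: 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            biomass,
        ],
        biomass_id="biomass",
    ).validate()
    return model, Medium(name=f"{carbon_id}_medium", uptake_limits={e: uptake})


def make_multichain_model(
    carbons: dict[str, tuple[float, float]], model_id: str = "multichain"
) -> tuple[MetabolicModel, Medium]:
    """Several carbon chains feeding one precursor pool.

    ``carbons`` maps carbon id -> (yield, uptake); the FBA optimum is the
    sum of ``yield * uptake`` over chains.
    """
    mets = [Metabolite(id="prec_c", compartment="c")]
    rxns = [Reaction(id="biomass", stoichiometry={"prec_c": -1.0},
                     lower_bound=0.0, upper_bound=1000.0, is_biomass=True)]
    limits = {}
    for cid, (y, up) in sorted(carbons.items()):
        e, c = f"{cid}_e", f"{cid}_c"
        mets += [Metabolite(id=e, compartment="e"), Metabolite(id=c, compartment="c")]
        rxns += [
            Reaction(id=f"EX_{e}", stoichiometry={e: -1.0},
                     lower_bound=-up, upper_bound=1000.0, is_exchange=True),
            Reaction(id=f"T_{cid}", stoichiometry={e: -1.0, c: 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id=f"CONV_{cid}", stoichiometry={c: -1.0, "prec_c": y},
                     lower_bound=0.0, upper_bound=1000.0),
        ]
        limits[e] = up
    model = MetabolicModel(id=model_id, metabolites=mets, reactions=rxns,
                           biomass_id="biomass").validate()
    return model, Medium(name="multichain_medium", uptake_limits=limits)


def make_fermenter_model(model_id: str = "fermenter") -> tuple[MetabolicModel, Medium]:
    """Glucose consumer that can secrete acetate (byproduct-screen fixture).

    Growth route: glc -> precursor (yield 0.5); fermentation route:
    glc -> 2 acetate, exported.  Acetate is producible; glucose cannot be
    net-exported (no internal source of extracellular glucose).
    """
    model = MetabolicModel(
        id=model_id,
        metabolites=[
            Metabolite(id="glc_e", compartment="e"),
            Metabolite(id="glc_c", compartment="c"),
            Metabolite(id="prec_c", compartment="c"),
            Metabolite(id="ac_c", compartment="c"),
            Metabolite(id="ac_e", compartment="e"),
        ],
        reactions=[
            Reaction(id="EX_glc_e", stoichiometry={"glc_e": -1.0},
                     lower_bound=-10.0, upper_bound=1000.0, is_exchange=True),
            Reaction(id="EX_ac_e", stoichiometry={"ac_e": -1.0},
                     lower_bound=0.0, upper_bound=1000.0, is_exchange=True),
            Reaction(id="T_glc", stoichiometry={"glc_e": -1.0, "glc_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="CONV_glc", stoichiometry={"glc_c": -1.0, "prec_c": 0.5},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="FERM", stoichiometry={"glc_c": -1.0, "ac_c": 2.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="T_ac_out", stoichiometry={"ac_c": -1.0, "ac_e": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="biomass", stoichiometry={"prec_c": -1.0},
                     lower_bound=0.0, upper_bound=1000.0, is_biomass=True),
        ],
        biomass_id="biomass",
    ).validate()
    return model, Medium(name="glc_medium", uptake_limits={"glc_e": 10.0})


def make_random_toy_model(
    rng: np.random.Generator, model_id: str = "random_toy"
) -> tuple[MetabolicModel, Medium]:
    """Random feasible branched chain for property tests (FVA containment,
    monotonicity): 2-4 sequential conversions with random yields, optional
    secreted byproduct and dead-end branch, random uptake limit."""
    n_steps = int(rng.integers(2, 5))
    uptake = float(rng.uniform(2.0, 20.0))
    mets = [Metabolite(id="s_e", compartment="e"),
            Metabolite(id="m0_c", compartment="c")]
    rxns = [
        Reaction(id="EX_s_e", stoichiometry={"s_e": -1.0},
                 lower_bound=-uptake, upper_bound=1000.0, is_exchange=True),
        Reaction(id="T_s", stoichiometry={"s_e": -1.0, "m0_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
    ]
    for i in range(n_steps):
        mets.append(Metabolite(id=f"m{i + 1}_c", compartment="c"))
        rxns.append(Reaction(
            id=f"R{i}",
            stoichiometry={f"m{i}_c": -1.0, f"m{i + 1}_c": float(rng.uniform(0.3, 1.0))},
            lower_bound=0.0, upper_bound=1000.0,
        ))
    if rng.random() < 0.5:  # secreted byproduct branch
        mets += [Metabolite(id="b_c", compartment="c"),
                 Metabolite(id="b_e", compartment="e")]
        rxns += [
            Reaction(id="R_byp", stoichiometry={"m1_c": -1.0, "b_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="T_b_out", stoichiometry={"b_c": -1.0, "b_e": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="EX_b_e", stoichiometry={"b_e": -1.0},
                     lower_bound=0.0, upper_bound=1000.0, is_exchange=True),
        ]
    if rng.random() < 0.5:  # dead-end branch (blocked reaction)
        mets.append(Metabolite(id="dead_c", compartment="c"))
        rxns.append(Reaction(id="R_dead",
                             stoichiometry={"m0_c": -1.0, "dead_c": 1.0},
                             lower_bound=0.0, upper_bound=0.0))
    rxns.append(Reaction(id="biomass", stoichiometry={f"m{n_steps}_c": -1.0},
                         lower_bound=0.0, upper_bound=1000.0, is_biomass=True))
    model = MetabolicModel(id=model_id, metabolites=mets, reactions=rxns,
                           biomass_id="biomass").validate()
    return model, Medium(name="toy_medium", uptake_limits={"s_e": uptake})


# ---------------------------------------------------------------------------
# Gap-fill fixtures
# ---------------------------------------------------------------------------

def make_gapfill_fixture(
    n_decoys: int = 3,
) -> tuple[MetabolicModel, list[Reaction], Medium, str]:
    """Chain model with its transport reaction removed, plus a pool holding
    the missing transport and ``n_decoys`` useless reactions.

    Returns (broken model, pool, medium, id of the reaction that fixes it).
    """
    model, medium = make_chain_model(yield_=0.5, uptake=10.0, carbon_id="glc",
                                     model_id="broken_chain")
    model.reactions = [r for r in model.reactions if r.id != "T_glc"]
    needed = Reaction(id="POOL_T_glc", stoichiometry={"glc_e": -1.0, "glc_c": 1.0},
                      lower_bound=0.0, upper_bound=1000.0)
    pool = [needed]
    for i in range(n_decoys):
        if i % 2 == 0:  # cytosolic sink
            pool.append(Reaction(id=f"POOL_sink{i}",
                                 stoichiometry={"glc_c": -1.0},
                                 lower_bound=0.0, upper_bound=1000.0))
        else:  # reverse transport (useless for growth)
            pool.append(Reaction(id=f"POOL_rev{i}",
                                 stoichiometry={"glc_c": -1.0, "glc_e": 1.0},
                                 lower_bound=0.0, upper_bound=1000.0))
    return model, pool, medium, needed.id


# ---------------------------------------------------------------------------
# Interaction-pair scenarios with planted labels
# ---------------------------------------------------------------------------

def _member(model_id, mets, rxns) -> MetabolicModel:
    return MetabolicModel(id=model_id, metabolites=mets, reactions=rxns,
                          biomass_id="biomass").validate()


def _ex(met, uptake=0.0, ub=1000.0) -> Reaction:
    return Reaction(id=f"EX_{met}", stoichiometry={met: -1.0},
                    lower_bound=-uptake, upper_bound=ub, is_exchange=True)


def _t(name, src, dst) -> Reaction:
    return Reaction(id=name, stoichiometry={src: -1.0, dst: 1.0},
                    lower_bound=0.0, upper_bound=1000.0)


def make_interaction_pairs() -> list[dict]:
    """Planted pair scenarios covering the four named interaction labels.

    Each entry is ``{"a", "b", "medium", "expected"}``; the expected labels
    are derived from the LP structure (hand-checkable at this size).
    """
    scenarios = []

    # competition: identical glucose users sharing one finite pool
    comp_a, medium = make_chain_model(model_id="comp_a")
    comp_b, _ = make_chain_model(model_id="comp_b")
    scenarios.append({"a": comp_a, "b": comp_b, "medium": medium,
                      "expected": "competition"})

    # mutualism: obligate cross-feeders (A needs B's y, B needs A's x)
    mut_a = _member(
        "mut_a",
        [Metabolite(id="glc_e", compartment="e"),
         Metabolite(id="glc_c", compartment="c"),
         Metabolite(id="x_c", compartment="c"),
         Metabolite(id="x_e", compartment="e"),
         Metabolite(id="y_e", compartment="e"),
         Metabolite(id="y_c", compartment="c")],
        [_ex("glc_e", 10.0), _ex("x_e"), _ex("y_e"),
         _t("T_glc", "glc_e", "glc_c"), _t("T_y_in", "y_e", "y_c"),
         _t("T_x_out", "x_c", "x_e"),
         Reaction(id="biomass",
                  stoichiometry={"glc_c": -2.0, "y_c": -0.1, "x_c": 1.0},
                  lower_bound=0.0, upper_bound=1000.0, is_biomass=True)],
    )
    mut_b = _member(
        "mut_b",
        [Metabolite(id="fru_e", compartment="e"),
         Metabolite(id="fru_c", compartment="c"),
         Metabolite(id="x_e", compartment="e"),
         Metabolite(id="x_c", compartment="c"),
         Metabolite(id="y_c", compartment="c"),
         Metabolite(id="y_e", compartment="e")],
        [_ex("fru_e", 10.0), _ex("x_e"), _ex("y_e"),
         _t("T_fru", "fru_e", "fru_c"), _t("T_x_in", "x_e", "x_c"),
         _t("T_y_out", "y_c", "y_e"),
         Reaction(id="biomass",
                  stoichiometry={"fru_c": -2.0, "x_c": -0.1, "y_c": 1.0},
                  lower_bound=0.0, upper_bound=1000.0, is_biomass=True)],
    )
    scenarios.append({
        "a": mut_a, "b": mut_b,
        "medium": Medium(name="glc_fru",
                         uptake_limits={"glc_e": 10.0, "fru_e": 10.0}),
        "expected": "mutualism",
    })

    # commensalism: donor's free byproduct z feeds an otherwise-starved B
    com_a = _member(
        "com_a",
        [Metabolite(id="glc_e", compartment="e"),
         Metabolite(id="glc_c", compartment="c"),
         Metabolite(id="z_c", compartment="c"),
         Metabolite(id="z_e", compartment="e")],
        [_ex("glc_e", 10.0), _ex("z_e"),
         _t("T_glc", "glc_e", "glc_c"), _t("T_z_out", "z_c", "z_e"),
         Reaction(id="biomass", stoichiometry={"glc_c": -2.0, "z_c": 1.0},
                  lower_bound=0.0, upper_bound=1000.0, is_biomass=True)],
    )
    com_b = _member(
        "com_b",
        [Metabolite(id="z_e", compartment="e"),
         Metabolite(id="z_c", compartment="c")],
        [_ex("z_e"), _t("T_z_in", "z_e", "z_c"),
         Reaction(id="biomass", stoichiometry={"z_c": -1.0},
                  lower_bound=0.0, upper_bound=1000.0, is_biomass=True)],
    )
    scenarios.append({
        "a": com_a, "b": com_b,
        "medium": Medium(name="glc", uptake_limits={"glc_e": 10.0}),
        "expected": "commensalism",
    })

    # parasitism: B steals shared glucose and needs A's secreted vitamin v
    par_a = _member(
        "par_a",
        [Metabolite(id="glc_e", compartment="e"),
         Metabolite(id="glc_c", compartment="c"),
         Metabolite(id="v_c", compartment="c"),
         Metabolite(id="v_e", compartment="e")],
        [_ex("glc_e", 10.0), _ex("v_e"),
         _t("T_glc", "glc_e", "glc_c"), _t("T_v_out", "v_c", "v_e"),
         Reaction(id="biomass", stoichiometry={"glc_c": -2.0, "v_c": 1.0},
                  lower_bound=0.0, upper_bound=1000.0, is_biomass=True)],
    )
    par_b = _member(
        "par_b",
        [Metabolite(id="glc_e", compartment="e"),
         Metabolite(id="glc_c", compartment="c"),
         Metabolite(id="v_e", compartment="e"),
         Metabolite(id="v_c", compartment="c")],
        [_ex("glc_e", 10.0), _ex("v_e"),
         _t("T_glc_b", "glc_e", "glc_c"), _t("T_v_in", "v_e", "v_c"),
         Reaction(id="biomass", stoichiometry={"glc_c": -2.0, "v_c": -0.05},
                  lower_bound=0.0, upper_bound=1000.0, is_biomass=True)],
    )
    scenarios.append({
        "a": par_a, "b": par_b,
        "medium": Medium(name="glc", uptake_limits={"glc_e": 10.0}),
        "expected": "parasitism",
    })
    return scenarios


# ---------------------------------------------------------------------------
# Six-member community whose label mix depends on the medium
# ---------------------------------------------------------------------------

RICH_CARBONS = ("r1", "r2", "r3")


def make_six_member_community() -> tuple[list[MetabolicModel], Medium, Medium]:
    """Six members, a rich medium and a single-carbon minimal medium.

    On the rich medium (three shared finite carbon sources plus the vitamin
    ``v``) every pair competes.  On glucose-minimal, the dependency
    structure surfaces: M4 needs the vitamin that only M1 secretes while
    stealing shared glucose (parasitism), M5 can only grow on M2's acetate
    byproduct (commensalism), glucose users compete, and pairs with a
    non-grower are neutral.
    """

    def rich_parts(tag: str):
        mets, rxns = [], []
        for r in RICH_CARBONS:
            mets += [Metabolite(id=f"{r}_e", compartment="e"),
                     Metabolite(id=f"{r}_c", compartment="c")]
            rxns += [
                _ex(f"{r}_e"), _t(f"T_{r}_{tag}", f"{r}_e", f"{r}_c"),
                Reaction(id=f"CONV_{r}_{tag}",
                         stoichiometry={f"{r}_c": -1.0, "prec_c": 0.5},
                         lower_bound=0.0, upper_bound=1000.0),
            ]
        return mets, rxns

    def glc_parts(tag: str, byproducts: dict[str, float] | None = None):
        stoich = {"glc_c": -1.0, "prec_c": 0.5}
        stoich.update(byproducts or {})
        return (
            [Metabolite(id="glc_e", compartment="e"),
             Metabolite(id="glc_c", compartment="c")],
            [_ex("glc_e"), _t(f"T_glc_{tag}", "glc_e", "glc_c"),
             Reaction(id=f"CONV_glc_{tag}", stoichiometry=stoich,
                      lower_bound=0.0, upper_bound=1000.0)],
        )

    def biomass() -> Reaction:
        return Reaction(id="biomass", stoichiometry={"prec_c": -1.0},
                        lower_bound=0.0, upper_bound=1000.0, is_biomass=True)

    members = []

    # M1: glucose user secreting vitamin v during glucose growth
    mets, rxns = rich_parts("m1")
    gm, gr = glc_parts("m1", {"v_c": 0.05})
    mets += gm + [Metabolite(id="prec_c", compartment="c"),
                  Metabolite(id="v_c", compartment="c"),
                  Metabolite(id="v_e", compartment="e")]
    rxns += gr + [_ex("v_e"), _t("T_v_out_m1", "v_c", "v_e")]
    members.append(_member("M1", mets, rxns + [biomass()]))

    # M2: glucose user secreting acetate during glucose growth
    mets, rxns = rich_parts("m2")
    gm, gr = glc_parts("m2", {"ac_c": 0.2})
    mets += gm + [Metabolite(id="prec_c", compartment="c"),
                  Metabolite(id="ac_c", compartment="c"),
                  Metabolite(id="ac_e", compartment="e")]
    rxns += gr + [_ex("ac_e"), _t("T_ac_out_m2", "ac_c", "ac_e")]
    members.append(_member("M2", mets, rxns + [biomass()]))

    # M3, M6: plain glucose + rich-carbon users
    for mid, tag in (("M3", "m3"), ("M6", "m6")):
        mets, rxns = rich_parts(tag)
        gm, gr = glc_parts(tag)
        mets += gm + [Metabolite(id="prec_c", compartment="c")]
        members.append(_member(mid, mets, rxns + gr + [biomass()]))

    # M4: glucose user auxotrophic for vitamin v
    mets, rxns = rich_parts("m4")
    gm, gr = glc_parts("m4")
    mets += gm + [Metabolite(id="prec_c", compartment="c"),
                  Metabolite(id="v_e", compartment="e"),
                  Metabolite(id="v_c", compartment="c")]
    rxns += gr + [_ex("v_e"), _t("T_v_in_m4", "v_e", "v_c")]
    bm4 = Reaction(id="biomass", stoichiometry={"prec_c": -1.0, "v_c": -0.05},
                   lower_bound=0.0, upper_bound=1000.0, is_biomass=True)
    members.append(_member("M4", mets, rxns + [bm4]))

    # M5: no glucose route; grows on rich carbons or on acetate
    mets, rxns = rich_parts("m5")
    mets += [Metabolite(id="prec_c", compartment="c"),
             Metabolite(id="ac_e", compartment="e"),
             Metabolite(id="ac_c", compartment="c")]
    rxns += [_ex("ac_e"), _t("T_ac_in_m5", "ac_e", "ac_c"),
             Reaction(id="CONV_ac_m5", stoichiometry={"ac_c": -1.0, "prec_c": 0.3},
                      lower_bound=0.0, upper_bound=1000.0)]
    members.append(_member("M5", mets, rxns + [biomass()]))

    members.sort(key=lambda m: m.id)
    rich = Medium(name="rich",
                  uptake_limits={**{f"{r}_e": 6.0 for r in RICH_CARBONS},
                                 "v_e": 5.0})
    minimal = Medium(name="glc_minimal", uptake_limits={"glc_e": 10.0})
    return members, rich, minimal


def six_member_expected_labels() -> dict[str, dict[tuple[str, str], str]]:
    """Planted pair labels of the six-member community on both media."""
    members = ["M1", "M2", "M3", "M4", "M5", "M6"]
    rich = {pair: "competition" for pair in itertools.combinations(members, 2)}
    growers = {"M1", "M2", "M3", "M6"}  # grow alone on glucose-minimal
    minimal = {}
    for pair in itertools.combinations(members, 2):
        a, b = pair
        if set(pair) <= growers:
            minimal[pair] = "competition"
        elif set(pair) == {"M1", "M4"}:
            minimal[pair] = "parasitism"
        elif set(pair) == {"M2", "M5"}:
            minimal[pair] = "commensalism"
        else:
            minimal[pair] = "neutral"
    return {"rich": rich, "minimal": minimal}


# ---------------------------------------------------------------------------
# Invertase (secreted-enzyme) scenario
# ---------------------------------------------------------------------------

def make_invertase_scenario() -> tuple[MetabolicModel, MetabolicModel,
                                       EnzymeSpecies, Medium]:
    """Sucrose cross-feeding via an extracellular invertase.

    The bearer hydrolyses extracellular sucrose to extracellular glucose +
    fructose and grows on the monosaccharides; the non-bearer has no sucrose
    route at all and can only grow when someone else releases the
    monosaccharides.  The enzyme is additionally returned as an independent
    species (single conversion reaction, fixed abundance) for the dynamic
    simulator.
    """
    bearer = _member(
        "bearer",
        [Metabolite(id="suc_e", compartment="e"),
         Metabolite(id="glc_e", compartment="e"),
         Metabolite(id="fru_e", compartment="e"),
         Metabolite(id="glc_c", compartment="c"),
         Metabolite(id="fru_c", compartment="c")],
        [_ex("suc_e", 10.0), _ex("glc_e"), _ex("fru_e"),
         Reaction(id="INV_ext",
                  stoichiometry={"suc_e": -1.0, "glc_e": 1.0, "fru_e": 1.0},
                  lower_bound=0.0, upper_bound=1000.0),
         _t("T_glc", "glc_e", "glc_c"), _t("T_fru", "fru_e", "fru_c"),
         Reaction(id="biomass", stoichiometry={"glc_c": -1.0, "fru_c": -1.0},
                  lower_bound=0.0, upper_bound=1000.0, is_biomass=True)],
    )
    non_bearer = _member(
        "non_bearer",
        [Metabolite(id="glc_e", compartment="e"),
         Metabolite(id="fru_e", compartment="e"),
         Metabolite(id="glc_c", compartment="c"),
         Metabolite(id="fru_c", compartment="c")],
        [_ex("glc_e"), _ex("fru_e"),
         _t("T_glc_nb", "glc_e", "glc_c"), _t("T_fru_nb", "fru_e", "fru_c"),
         Reaction(id="biomass", stoichiometry={"glc_c": -1.0, "fru_c": -1.0},
                  lower_bound=0.0, upper_bound=1000.0, is_biomass=True)],
    )
    enzyme = EnzymeSpecies(
        id="invertase",
        stoichiometry={"suc_e": -1.0, "glc_e": 1.0, "fru_e": 1.0},
        rate_constant=5.0, abundance=1.0,
    ).validate()
    medium = Medium(name="sucrose", uptake_limits={"suc_e": 10.0})
    return bearer, non_bearer, enzyme, medium


# ---------------------------------------------------------------------------
# Hit tables with planted pathway presence
# ---------------------------------------------------------------------------

def make_pathway_definitions(
    n_pathways: int = 8, reactions_per: int = 5
) -> list[PathwayDefinition]:
    """Small pathway universe with one key reaction each and rotating
    categories (so strategy-trait counting is exercised)."""
    categories = ["Energy-Metabolism", "Antibiotic-Biosynthesis",
                  "Siderophores-Biosynthesis", "EPS", "Amino-Acid-Biosynthesis"]
    defs = []
    for i in range(n_pathways):
        rxns = [f"pwy{i}_rxn{j}" for j in range(reactions_per)]
        defs.append(PathwayDefinition(
            pathway_id=f"PWY-{i:03d}", name=f"pathway {i}",
            reaction_ids=rxns, key_reaction_ids=[rxns[0]],
            category=categories[i % len(categories)],
        ).validate())
    return defs


def make_hit_tables(
    definitions: list[PathwayDefinition],
    presence: pd.DataFrame,
    noise: float = 0.0,
    seed: int = 0,
) -> list[HitRecord]:
    """Hit records realizing a planted genome x pathway presence matrix.

    Present pathways get strong hits (bitscore in [200, 400], coverage in
    [0.8, 1.0]) for every reaction; absent pathways get strong hits for at
    most half of their reactions, never including the key reaction, plus
    sub-threshold decoy hits.  ``noise`` flips each reaction's hit strength
    independently with the given probability.
    """
    rng = np.random.default_rng(seed)
    hits: list[HitRecord] = []
    for genome in presence.index:
        for d in definitions:
            planted = bool(presence.loc[genome, d.pathway_id])
            n = len(d.reaction_ids)
            weak_cap = n // 2  # completeness <= 0.5, safely below the 66% rule
            for j, rxn in enumerate(d.reaction_ids):
                strong = planted or (rxn not in d.key_reaction_ids and j < weak_cap)
                if noise > 0 and rng.random() < noise:
                    strong = not strong
                if strong:
                    hits.append(HitRecord(
                        genome_id=genome, query_id=rxn,
                        bitscore=float(rng.uniform(200, 400)),
                        query_coverage=float(rng.uniform(0.8, 1.0)),
                    ))
                else:
                    hits.append(HitRecord(
                        genome_id=genome, query_id=rxn,
                        bitscore=float(rng.uniform(10, 45)),
                        query_coverage=float(rng.uniform(0.1, 0.6)),
                    ))
    return hits


def make_presence_matrix(
    genomes: list[str], definitions: list[PathwayDefinition],
    density: float = 0.6, seed: int = 0,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    mat = rng.random((len(genomes), len(definitions))) < density
    return pd.DataFrame(mat, index=genomes,
                        columns=[d.pathway_id for d in definitions])


# ---------------------------------------------------------------------------
# BIOLOG plates with planted substrate usage
# ---------------------------------------------------------------------------

PLATE_OD0 = 0.1
PLATE_WATER_FC = 0.2  # background raw fold change of the water well


def make_plate(
    usage: pd.DataFrame,
    fc_pos: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    step_min: int = 30,
) -> pd.DataFrame:
    """Tidy plate table realizing a planted strain x substrate usage matrix.

    Raw fold change per well = water background (+ ``fc_pos`` if the strain
    uses the substrate) + Gaussian noise; OD ramps linearly from 0.1 at t0
    to the 46-h endpoint on a 30-min grid.  At zero noise, binarized
    background-corrected fold changes reproduce ``usage`` exactly and the
    water well's corrected fold change is 0 by construction.
    """
    from .model_io import PLATE_T46_MIN

    rng = np.random.default_rng(seed)
    times = np.arange(0, PLATE_T46_MIN + 1, step_min)
    if times[-1] != PLATE_T46_MIN:
        times = np.append(times, PLATE_T46_MIN)
    rows = []
    for strain in usage.index:
        for substrate in list(usage.columns) + ["water"]:
            used = substrate != "water" and bool(usage.loc[strain, substrate])
            for rep in range(1, n_replicates + 1):
                fc_raw = PLATE_WATER_FC + (fc_pos if used else 0.0)
                if noise_sd > 0:
                    fc_raw += rng.normal(0.0, noise_sd)
                od_end = max(PLATE_OD0 * (1 + fc_raw), 1e-3)
                ods = PLATE_OD0 + (od_end - PLATE_OD0) * times / PLATE_T46_MIN
                for t, od in zip(times, ods):
                    rows.append((strain, substrate, rep, int(t), float(od)))
    return pd.DataFrame(rows, columns=["strain", "substrate", "replicate",
                                       "time_min", "od"])


def make_substrate_cluster_usage(
    strains: list[str], n_per_group: int = 6
) -> tuple[pd.DataFrame, pd.Series]:
    """Two planted substrate groups: group 0 used by the first half of the
    strains, group 1 by the second half; returns (usage, truth labels)."""
    half = len(strains) // 2
    subs, truth, data = [], {}, {}
    for g in range(2):
        for i in range(n_per_group):
            sub = f"grp{g}_sub{i}"
            subs.append(sub)
            truth[sub] = g
            data[sub] = [
                (idx < half) if g == 0 else (idx >= half)
                for idx in range(len(strains))
            ]
    usage = pd.DataFrame(data, index=strains)
    return usage, pd.Series(truth)


# ---------------------------------------------------------------------------
# Correlated 16S / pathway-vector structure
# ---------------------------------------------------------------------------

def _evolve_tree(
    ids: list[str],
    state: np.ndarray,
    rng: np.random.Generator,
    mutate,
    bl_lo: float = 0.04,
    bl_hi: float = 0.09,
    decay: float = 0.6,
    depth: int = 0,
) -> dict[str, np.ndarray]:
    """Evolve ``state`` down a random bifurcating tree over ``ids``.

    Branch lengths shrink geometrically with depth (factor ``decay``), so
    the deepest splits carry most divergence — the genus-vs-strain block
    structure of real 16S data, which keeps pairwise divergences spread well
    above the finite-length sampling noise.
    """
    if len(ids) == 1:
        return {ids[0]: state}
    k = int(rng.integers(1, len(ids)))
    order = rng.permutation(len(ids))
    left = [ids[i] for i in order[:k]]
    right = [ids[i] for i in order[k:]]
    out = {}
    for group in (left, right):
        bl = float(rng.uniform(bl_lo, bl_hi)) * decay ** depth
        out.update(_evolve_tree(group, mutate(state, bl), rng, mutate,
                                bl_lo, bl_hi, decay, depth + 1))
    return out


def _mutate_seq(rng):
    def inner(state, bl):
        seq = state.copy()
        hit = rng.random(seq.size) < bl
        seq[hit] = rng.integers(0, 4, size=int(hit.sum()))
        return seq
    return inner


def _mutate_bits(rng, rate_scale=2.0):
    def inner(state, bl):
        bits = state.copy()
        hit = rng.random(bits.size) < min(bl * rate_scale, 0.5)
        bits[hit] = 1 - bits[hit]
        return bits
    return inner


def coupling_fraction(target_rho: float) -> float:
    """Fraction of pathway columns tied to the 16S tree for a target
    pairwise-matrix correlation (variance-matching mixture calibration)."""
    if not (0.0 <= target_rho <= 1.0):
        raise ValueError("target rho must be in [0, 1]")
    if target_rho >= 1.0:
        return 1.0
    q = target_rho / np.sqrt(1.0 - target_rho ** 2)
    return float(q / (1.0 + q))


def make_correlated_16s_and_pathways(
    n: int = 30,
    target_rho: float = 0.6,
    seed: int = 0,
    seq_len: int = 700,
    n_pathways: int = 300,
) -> tuple[dict[str, str], pd.DataFrame]:
    """16S sequences and pathway vectors with coupled divergence structure.

    Sequences evolve down a random tree; a calibrated fraction of pathway
    columns evolves down the *same* tree (same branch lengths) and the rest
    down an independent tree, so the pairwise similarity matrices correlate
    at approximately ``target_rho``.  Byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ids = [f"iso{i:02d}" for i in range(n)]
    f = coupling_fraction(target_rho)
    n_shared = int(round(f * n_pathways))

    root_seq = rng.integers(0, 4, size=seq_len)
    root_shared = rng.integers(0, 2, size=n_shared)
    root_indep = rng.integers(0, 2, size=n_pathways - n_shared)

    # shared tree: sequence and the coupled pathway columns co-evolve
    state = np.concatenate([root_seq, root_shared])
    mut_seq, mut_bits = _mutate_seq(rng), _mutate_bits(rng)

    def mutate_joint(st, bl):
        return np.concatenate([mut_seq(st[:seq_len], bl),
                               mut_bits(st[seq_len:], bl)])

    joint = _evolve_tree(ids, state, rng, mutate_joint)
    indep = _evolve_tree(ids, root_indep, rng, _mutate_bits(rng)) \
        if n_pathways - n_shared else {i: np.empty(0, dtype=int) for i in ids}

    seqs = {i: "".join(BASES[b] for b in joint[i][:seq_len]) for i in ids}
    vectors = pd.DataFrame(
        {f"pwy{j:03d}": 0 for j in range(n_pathways)}, index=ids
    )
    for i in ids:
        vectors.loc[i] = np.concatenate([joint[i][seq_len:], indep[i]])
    return seqs, vectors.astype(int)


# ---------------------------------------------------------------------------
# UAST cohorts and phenotypes
# ---------------------------------------------------------------------------

#: trait archetypes for the three adaptive strategies
UAST_ARCHETYPES = {
    "C": dict(genome_size=7_000_000, antibiotic_pathways=8,
              catabolic_diversity=30, siderophore_pathways=4, auxotrophies=1,
              growth_rate=0.40, rrna_copies=3, eps_pathways=1),
    "S": dict(genome_size=4_000_000, antibiotic_pathways=1,
              catabolic_diversity=14, siderophore_pathways=0, auxotrophies=8,
              growth_rate=0.15, rrna_copies=1, eps_pathways=5),
    "R": dict(genome_size=4_500_000, antibiotic_pathways=1,
              catabolic_diversity=6, siderophore_pathways=0, auxotrophies=2,
              growth_rate=0.90, rrna_copies=7, eps_pathways=0),
}
#: relative trait noise of the cohort generator (biological + inference spread)
UAST_NOISE = 0.15


def make_uast_cohort(
    n_per_strategy: dict[str, int] | int = 13,
    noise: float = UAST_NOISE,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Isolate trait cohort around the three strategy archetypes.

    Gaussian noise with sd ``noise * archetype value`` (absolute floor for
    zero-valued traits) is added per trait; counts are rounded and clipped
    at zero.  Returns (traits, truth strategy labels).
    """
    if isinstance(n_per_strategy, int):
        n_per_strategy = {k: n_per_strategy for k in UAST_ARCHETYPES}
    rng = np.random.default_rng(seed)
    rows, truth = [], {}
    i = 0
    for strategy, arch in UAST_ARCHETYPES.items():
        for _ in range(n_per_strategy.get(strategy, 0)):
            iso = f"iso{i:03d}"
            i += 1
            row = {"isolate_id": iso}
            for trait, value in arch.items():
                sd = noise * (abs(value) if value else 1.0)
                x = value + rng.normal(0.0, sd)
                if trait != "growth_rate":
                    x = max(0.0, round(x))
                row[trait] = max(x, 1.0 if trait == "genome_size" else 0.0)
            rows.append(row)
            truth[iso] = strategy
    traits = pd.DataFrame(rows).set_index("isolate_id")
    return traits, pd.Series(truth, name="strategy")


def make_binary_traits(
    n_isolates: int = 60, n_traits: int = 20, prevalence: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    ids = [f"iso{i:03d}" for i in range(n_isolates)]
    mat = (rng.random((n_isolates, n_traits)) < prevalence).astype(int)
    return pd.DataFrame(mat, index=ids,
                        columns=[f"trait{j:02d}" for j in range(n_traits)])


def make_phenotypes(
    traits: pd.DataFrame,
    effects: dict[str, float],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.Series, dict[str, float]]:
    """Phenotype = sum of planted trait effects (in noise-sd units) + noise."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, noise_sd, size=len(traits))
    for trait, d in effects.items():
        y = y + d * noise_sd * traits[trait].to_numpy(dtype=float)
    return pd.Series(y, index=traits.index, name="bacterial_load"), dict(effects)


# ---------------------------------------------------------------------------
# On-disk scenario suite (inputs for the pipeline driver and CLI)
# ---------------------------------------------------------------------------

def write_suite(out_dir, seed: int = 0) -> dict:
    """Write a complete synthetic input suite plus ground-truth files.

    Produces: model JSONs and media CSVs (six-member community), a hit
    table and pathway definitions with planted presence, 16S FASTA and
    pathway vectors with coupled divergence, a BIOLOG plate with planted
    usage, a UAST trait cohort and a phenotype with planted effects.  The
    planted truth is serialized to ``truth.json``.  Pure function of the
    seed (byte-identical reruns).
    """
    import json
    from pathlib import Path

    from .model_io import write_fasta, write_hit_table, write_medium, \
        write_model, write_pathways

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"seed": seed}

    members, rich, minimal = make_six_member_community()
    (out / "models").mkdir(exist_ok=True)
    for m in members:
        write_model(m, out / "models" / f"{m.id}.json")
    write_medium(rich, out / "medium_rich.csv")
    write_medium(minimal, out / "medium_minimal.csv")
    truth["interaction_labels"] = {
        medium: {"|".join(k): v for k, v in labels.items()}
        for medium, labels in six_member_expected_labels().items()
    }

    defs = make_pathway_definitions()
    genomes = [m.id for m in members]
    presence = make_presence_matrix(genomes, defs, seed=seed)
    hits = make_hit_tables(defs, presence, noise=0.0, seed=seed)
    write_pathways(defs, out / "pathways.tsv")
    write_hit_table(hits, out / "hits.tsv")
    truth["pathway_presence"] = {
        g: presence.loc[g].astype(bool).to_dict() for g in genomes}

    seqs, vectors = make_correlated_16s_and_pathways(n=20, target_rho=0.6,
                                                     seed=seed)
    write_fasta(seqs, out / "16s.fasta")
    vectors.rename_axis("isolate_id").to_csv(out / "pathway_vectors.csv")
    truth["target_rho"] = 0.6

    strains = [f"strain{i}" for i in range(6)]
    usage, sub_truth = make_substrate_cluster_usage(strains)
    plate = make_plate(usage, noise_sd=0.05, seed=seed)
    plate.to_csv(out / "plate.csv", index=False)
    truth["substrate_clusters"] = sub_truth.to_dict()
    truth["substrate_usage"] = {s: usage.loc[s].astype(bool).to_dict()
                                for s in strains}

    traits, strategy_truth = make_uast_cohort(
        n_per_strategy={"C": 13, "S": 13, "R": 14}, seed=seed)
    traits.rename_axis("isolate_id").to_csv(out / "traits.csv")
    truth["strategies"] = strategy_truth.to_dict()

    binary = make_binary_traits(seed=seed)
    effects = {"trait00": 1.5}
    phenotype, _ = make_phenotypes(binary, effects, seed=seed)
    binary.rename_axis("isolate_id").to_csv(out / "binary_traits.csv")
    phenotype.rename_axis("isolate_id").reset_index().to_csv(
        out / "phenotype.csv", index=False)
    truth["phenotype_effects"] = effects

    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
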