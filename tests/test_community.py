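import itertools

import pytest

from repertoire import synth
from repertoire.community import (
    classify_interaction,
    community_fba,
    evaluate_pair,
    exchanged_metabolites,
    interaction_screen,
    join_models,
    monoculture_growth,
)


def test_join_merges_shared_pool(chain):
    a, _ = chain
    b = a.copy()
    b.id = "chain_copy"
    community = join_models(a, b)
    assert len([r for r in community.reactions if r.is_biomass]) == 2
    # one shared glc_e pool with a single community exchange
    ex = [r for r in community.reactions if r.is_exchange]
    assert [next(iter(r.stoichiometry)) for r in ex] == ["glc_e"]


def test_join_rejects_identical_ids(chain):
    a, _ = chain
    with pytest.raises(ValueError, match="differ"):
        join_models(a, a.copy())


def test_symmetric_competition_splits_evenly(chain):
    a, medium = chain
    b = a.copy()
    b.id = "chain_copy"
    j1, j2, status, _ = community_fba(join_models(a, b), medium)
    assert status == "optimal"
    assert j1 == pytest.approx(2.5, abs=1e-5)
    assert j2 == pytest.approx(2.5, abs=1e-5)


def test_stage2_preserves_stage1_sum(interaction_pairs):
    """The max-min split must reproduce the maximal biomass sum."""
    from repertoire.community import _community_lp
    from repertoire.fba_core import solve_lp
    import numpy as np

    for sc in interaction_pairs:
        community = join_models(sc["a"], sc["b"])
        S, idx, bounds, A_ub, b_ub, rxn_ids = _community_lp(
            community, sc["medium"])
        c = np.zeros(len(rxn_ids))
        for k in community.member_ids:
            c[idx[community.biomass_ids[k]]] = 1.0
        _, total, _ = solve_lp(c, S, bounds, maximize=True, A_ub=A_ub, b_ub=b_ub)
        j1, j2, _, _ = community_fba(community, sc["medium"])
        assert j1 + j2 == pytest.approx(total, abs=1e-5)


def test_zero_coupling_forces_zero_flux(chain):
    """With c = 0 a member that cannot grow cannot carry any flux, so two
    members cannot even take up substrate: joint growth collapses to 0 only
    when growth itself is impossible."""
    a, medium = chain
    b = a.copy()
    b.id = "chain_copy"
    j1, j2, status, fluxes = community_fba(join_models(a, b, c=0.0), medium)
    # c = 0 couples |v| <= 0 for all internal reactions: no growth possible
    assert j1 == pytest.approx(0.0, abs=1e-8)
    assert j2 == pytest.approx(0.0, abs=1e-8)


def test_no_carbon_zero_growth(chain):
    from repertoire.model_io import Medium

    a, _ = chain
    b = a.copy()
    b.id = "chain_copy"
    j1, j2, _, _ = community_fba(join_models(a, b),
                                 Medium(name="none", uptake_limits={}))
    assert (j1, j2) == (pytest.approx(0.0, abs=1e-9),
                        pytest.approx(0.0, abs=1e-9))


def test_inert_partner_leaves_growth_unchanged(chain):
    a, medium = chain
    s = monoculture_growth(a, medium)
    assert s == pytest.approx(5.0, abs=1e-5)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("s1,s2,j1,j2,label", [
    (1, 1, 2, 2, "mutualism"),
    (1, 1, 0.5, 0.5, "competition"),
    (1, 1, 0.5, 2.0, "parasitism"),
    (1, 1, 2.0, 0.5, "parasitism"),
    (1, 0, 1, 0.5, "commensalism"),
    (1, 1, 1, 0.5, "amensalism"),
    (1, 1, 1, 1, "neutral"),
    (0, 0, 0, 0, "neutral"),
])
def test_classifier_definitions(s1, s2, j1, j2, label):
    assert classify_interaction(s1, s2, j1, j2) == label


def test_classifier_total_over_grid():
    """Every (s, j) combination maps to exactly one label."""
    values = [0.0, 0.5, 1.0, 1.5]
    from repertoire.community import LABELS

    for s1, s2, j1, j2 in itertools.product(values, repeat=4):
        assert classify_interaction(s1, s2, j1, j2) in LABELS


def test_classifier_rejects_negative():
    with pytest.raises(ValueError):
        classify_interaction(-1, 0, 0, 0)


# ---------------------------------------------------------------------------
# Planted scenarios
# ---------------------------------------------------------------------------

def test_planted_pair_labels(interaction_pairs):
    for sc in interaction_pairs:
        res = evaluate_pair(sc["a"], sc["b"], sc["medium"])
        assert res.label == sc["expected"], sc["expected"]


@pytest.mark.parametrize("coupling", [100.0, 400.0, 1000.0])
def test_labels_stable_across_coupling(interaction_pairs, coupling):
    for sc in interaction_pairs:
        res = evaluate_pair(sc["a"], sc["b"], sc["medium"], c=coupling)
        assert res.label == sc["expected"]


def test_screen_requires_two_models(chain):
    model, medium = chain
    with pytest.raises(ValueError):
        interaction_screen([model], medium)


def test_six_member_medium_dependence():
    """Label mix flips from pure competition (rich medium) to a mix with
    parasitism (single-carbon minimal medium)."""
    members, rich, minimal = synth.make_six_member_community()
    expected = synth.six_member_expected_labels()
    for name, medium in (("rich", rich), ("minimal", minimal)):
        results, fractions = interaction_screen(members, medium)
        for r in results:
            assert r.label == expected[name][r.member_ids], (name, r)
    _, rich_frac = interaction_screen(members, rich)
    assert rich_frac["competition"] == pytest.approx(1.0)
    _, min_frac = interaction_screen(members, minimal)
    assert min_frac["parasitism"] > 0
    assert min_frac["competition"] < 1.0


# ---------------------------------------------------------------------------
# Exchanged metabolites
# ---------------------------------------------------------------------------

def test_exchanged_metabolites_cross_feeding(interaction_pairs):
    commensal = next(sc for sc in interaction_pairs
                     if sc["expected"] == "commensalism")
    community = join_models(commensal["a"], commensal["b"])
    flows = exchanged_metabolites(community, commensal["medium"])
    assert [(m, d) for m, d, _ in flows] == [("z_e", "com_a")]
    assert flows[0][2] > 1.0


def test_exchanged_metabolites_empty_for_competitors(chain):
    a, medium = chain
    b = a.copy()
    b.id = "chain_copy"
    assert exchanged_metabolites(join_models(a, b), medium) == []


def test_independent_carbon_sources_no_exchange():
    a, med_a = synth.make_chain_model(carbon_id="glc", model_id="on_glc")
    b, med_b = synth.make_chain_model(carbon_id="fru", model_id="on_fru")
    from repertoire.model_io import Medium

    medium = Medium(name="both", uptake_limits={"glc_e": 10.0, "fru_e": 10.0})
    assert exchanged_metabolites(join_models(a, b), medium) == []
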