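import itertools

import numpy as np
import pandas as pd
import pytest

from repertoire import synth
from repertoire.stats import (
    benjamini_hochberg,
    spearman_perm,
    wilcoxon_rank_sum,
)
from repertoire.uast import (
    IsolateTraits,
    score_strategies,
    strategy_phenotype_tests,
    traits_frame,
)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_hand_worked_vector():
    assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04, 0.04, 0.04, 0.04])


def test_bh_degenerate_cases():
    assert benjamini_hochberg([0.37]) == pytest.approx([0.37])
    assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])
    with pytest.raises(ValueError):
        benjamini_hochberg([-0.1])


def test_bh_matches_reference_implementation(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(50):
        p = rng.random(int(rng.integers(1, 40)))
        expected = multipletests(p, method="fdr_bh")[1]
        assert benjamini_hochberg(p) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def test_wilcoxon_exact_enumeration_oracle():
    """{1,2,3} vs {4,5,6}: enumerate all C(6,3) = 20 assignments; 2 are as
    extreme as the observed rank sum, so two-sided p = 0.1."""
    x, y = [1, 2, 3], [4, 5, 6]
    pooled = sorted(x + y)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)
    count = 0
    for combo in itertools.combinations(range(1, 7), 3):
        rank_sum = sum(combo)
        if abs(rank_sum - 10.5) >= abs(obs - 10.5):  # 10.5 = null mean
            count += 1
    assert count / 20 == pytest.approx(0.1)
    _, p = wilcoxon_rank_sum(x, y, mode="exact")
    assert p == pytest.approx(0.1)


def test_wilcoxon_identical_groups():
    _, p = wilcoxon_rank_sum([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
    assert p == pytest.approx(1.0)


def test_wilcoxon_exact_vs_normal_agreement(rng):
    x = rng.normal(0, 1, 10)
    y = rng.normal(0.5, 1, 10)
    _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
    _, p_norm = wilcoxon_rank_sum(x, y, mode="normal")
    assert abs(p_exact - p_norm) < 0.02


# ---------------------------------------------------------------------------
# Permutation association
# ---------------------------------------------------------------------------

def test_perfect_trait_min_p():
    """A trait identical to the phenotype ranks: rho = 1 and the smallest
    attainable permutation p, 1/(n_random + 1)."""
    n = 20
    traits = pd.DataFrame({"t": np.arange(n)}, index=[f"i{k}" for k in range(n)])
    pheno = pd.Series(np.arange(n, dtype=float), index=traits.index)
    (res,) = spearman_perm(traits, pheno, n_random=99, seed=0)
    assert res.rho == pytest.approx(1.0)
    assert res.p_perm == pytest.approx(1 / 100)


def test_constant_phenotype_rejected():
    traits = pd.DataFrame({"t": [0, 1, 0, 1]}, index=list("abcd"))
    with pytest.raises(ValueError, match="constant"):
        spearman_perm(traits, pd.Series([1.0] * 4, index=list("abcd")))


def test_p_invariant_to_monotone_phenotype_transform():
    traits = synth.make_binary_traits(n_isolates=30, n_traits=5, seed=1)
    pheno, _ = synth.make_phenotypes(traits, {"trait01": 1.0}, seed=1)
    res1 = spearman_perm(traits, pheno, n_random=199, seed=3)
    res2 = spearman_perm(traits, np.exp(pheno), n_random=199, seed=3)
    for r1, r2 in zip(res1, res2):
        assert r1.rho == pytest.approx(r2.rho)
        assert r1.p_perm == pytest.approx(r2.p_perm)


def test_null_calibration_type_one_error():
    """Independent trait and phenotype: rejection rate at 0.05 is nominal."""
    rng = np.random.default_rng(7)
    reps, rejections = 300, 0
    idx = [f"i{k}" for k in range(30)]
    for _ in range(reps):
        traits = pd.DataFrame({"t": rng.integers(0, 2, 30)}, index=idx)
        pheno = pd.Series(rng.normal(size=30), index=idx)
        (res,) = spearman_perm(traits, pheno, n_random=99,
                               seed=int(rng.integers(2**31)))
        rejections += res.p_perm <= 0.05
    assert 0.02 <= rejections / reps <= 0.08


def test_planted_effect_ranks_first():
    traits = synth.make_binary_traits(n_isolates=60, seed=2)
    pheno, _ = synth.make_phenotypes(traits, {"trait00": 1.5}, seed=2)
    res = spearman_perm(traits, pheno, n_random=999, seed=2)
    best = max(res, key=lambda r: abs(r.rho))
    assert best.trait_id == "trait00"
    assert best.q < 0.05


# ---------------------------------------------------------------------------
# UAST scoring
# ---------------------------------------------------------------------------

def archetype_cohort():
    traits, truth = synth.make_uast_cohort(
        n_per_strategy={"C": 4, "S": 4, "R": 4}, noise=0.0, seed=0)
    return traits, truth


def test_pure_archetypes_score_one():
    traits, truth = archetype_cohort()
    for s in score_strategies(traits):
        assert s.assigned == truth[s.isolate_id]
        assert {s.c_score, s.s_score, s.r_score} <= {x / 12 for x in range(13)}
        assert 0 <= min(s.c_score, s.s_score, s.r_score)
        assert max(s.c_score, s.s_score, s.r_score) <= 1.0


def test_assigned_consistent_with_argmax_and_ties():
    traits, _ = archetype_cohort()
    for s in score_strategies(traits):
        scores = {"C": s.c_score, "S": s.s_score, "R": s.r_score}
        best = max(scores.values())
        winners = [k for k, v in scores.items() if v == best]
        assert s.assigned == (winners[0] if len(winners) == 1 else "mixed")


def test_tie_yields_mixed():
    # two isolates tied on every criterion split points identically
    rows = []
    for i, (gs, anti, cat, sid, aux, gr, rrna, eps) in enumerate([
        (7e6, 8, 30, 4, 8, 0.1, 1, 5),   # top C criteria AND top S criteria
        (4e6, 0, 10, 0, 0, 0.9, 8, 0),
        (4e6, 0, 12, 0, 1, 0.8, 7, 0),
        (5e6, 1, 15, 1, 2, 0.5, 4, 1),
    ]):
        rows.append(IsolateTraits(
            isolate_id=f"i{i}", genome_size=int(gs), antibiotic_pathways=anti,
            catabolic_diversity=cat, siderophore_pathways=sid,
            auxotrophies=aux, growth_rate=gr, rrna_copies=rrna,
            eps_pathways=eps))
    scores = score_strategies(rows)
    assert scores[0].c_score == scores[0].s_score == 1.0
    assert scores[0].assigned == "mixed"


def test_scoring_invariant_to_trait_rescaling():
    traits, _ = synth.make_uast_cohort(n_per_strategy=5, seed=3)
    base = score_strategies(traits)
    scaled = traits.copy()
    scaled["genome_size"] = scaled["genome_size"] * 1000.0
    rescored = score_strategies(scaled)
    for a, b in zip(base, rescored):
        assert (a.c_score, a.s_score, a.r_score, a.assigned) == \
            (b.c_score, b.s_score, b.r_score, b.assigned)


def test_cohort_too_small():
    traits, _ = synth.make_uast_cohort(n_per_strategy={"C": 1, "S": 1, "R": 1},
                                       seed=0)
    with pytest.raises(ValueError, match="cohort"):
        score_strategies(traits)


def test_planted_archetype_recovery_rate():
    traits, truth = synth.make_uast_cohort(
        n_per_strategy={"C": 13, "S": 13, "R": 14}, seed=11)
    scores = score_strategies(traits)
    correct = sum(s.assigned == truth[s.isolate_id] for s in scores)
    assert correct / len(scores) >= 0.9


def test_strategy_phenotype_tests_ruderal_low():
    traits, truth = synth.make_uast_cohort(n_per_strategy=5, noise=0.0, seed=0)
    scores = score_strategies(traits)
    rng = np.random.default_rng(0)
    loads = {
        s.isolate_id: (1.0 if s.assigned == "R" else 10.0) + rng.normal(0, .1)
        for s in scores
    }
    out = strategy_phenotype_tests(scores, loads)
    assert out["p_ruderal_vs_others"] < 0.01
    # degenerate loads -> rho is NA
    flat = dict.fromkeys(loads, 5.0)
    out2 = strategy_phenotype_tests(scores, flat)
    assert np.isnan(out2["rho_load_vs_score_CS"]) or \
        np.isnan(out2["p_load_vs_score_CS"])
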