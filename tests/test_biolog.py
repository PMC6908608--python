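import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from repertoire import synth
from repertoire.biolog import (
    binarize_profile,
    fold_change,
    model_agreement,
    strain_dendrogram,
    substrate_kmeans,
)
from repertoire.model_io import PLATE_T0_MIN, PLATE_T46_MIN, ParseError


def tidy_plate(wells):
    """wells: {(strain, substrate, replicate): (od0, od46)}"""
    rows = []
    for (s, sub, rep), (od0, od46) in wells.items():
        rows.append((s, sub, rep, PLATE_T0_MIN, od0))
        rows.append((s, sub, rep, PLATE_T46_MIN, od46))
    return pd.DataFrame(rows, columns=["strain", "substrate", "replicate",
                                       "time_min", "od"])


def test_fold_change_hand_computed():
    """OD 0.1 -> 0.5 with water fold change 0.2 gives 3.8."""
    plate = tidy_plate({
        ("s1", "glucose", 1): (0.1, 0.5),
        ("s1", "water", 1): (0.1, 0.12),   # raw FC 0.2
    })
    profile = fold_change(plate)
    assert profile.loc["s1", "glucose"] == pytest.approx(3.8)


def test_fold_change_water_like_substrate_and_negative():
    plate = tidy_plate({
        ("s1", "same_as_water", 1): (0.1, 0.12),
        ("s1", "shrinking", 1): (0.2, 0.1),
        ("s1", "water", 1): (0.1, 0.12),
    })
    profile = fold_change(plate)
    assert profile.loc["s1", "same_as_water"] == pytest.approx(0.0)
    assert profile.loc["s1", "shrinking"] == pytest.approx(-0.7)


def test_fold_change_replicates_averaged():
    plate = tidy_plate({
        ("s1", "glc", 1): (0.1, 0.3), ("s1", "glc", 2): (0.1, 0.5),
        ("s1", "water", 1): (0.1, 0.1), ("s1", "water", 2): (0.1, 0.1),
    })
    assert fold_change(plate).loc["s1", "glc"] == pytest.approx(3.0)


def test_fold_change_errors():
    with pytest.raises(ParseError, match="zero"):
        fold_change(tidy_plate({("s1", "glc", 1): (0.0, 0.5),
                                ("s1", "water", 1): (0.1, 0.1)}))
    plate = tidy_plate({("s1", "glc", 1): (0.1, 0.5),
                        ("s1", "water", 1): (0.1, 0.1)})
    with pytest.raises(ParseError):
        fold_change(plate[plate["time_min"] != PLATE_T46_MIN])


def test_fold_change_matches_spreadsheet_recomputation():
    """Independent cell-by-cell recomputation on a 5x5 planted fixture."""
    strains = [f"s{i}" for i in range(5)]
    usage, _ = synth.make_substrate_cluster_usage(strains, n_per_group=3)
    plate = synth.make_plate(usage, fc_pos=2.5, noise_sd=0.03, seed=9)
    profile = fold_change(plate)
    ends = plate[plate["time_min"].isin([PLATE_T0_MIN, PLATE_T46_MIN])]
    for strain in strains:
        sub_df = ends[ends["strain"] == strain]
        water_fc = {}
        for rep, grp in sub_df[sub_df["substrate"] == "water"].groupby("replicate"):
            od = grp.set_index("time_min")["od"]
            water_fc[rep] = (od[PLATE_T46_MIN] - od[PLATE_T0_MIN]) / od[PLATE_T0_MIN]
        for substrate in usage.columns:
            fcs = []
            wells = sub_df[sub_df["substrate"] == substrate]
            for rep, grp in wells.groupby("replicate"):
                od = grp.set_index("time_min")["od"]
                raw = (od[PLATE_T46_MIN] - od[PLATE_T0_MIN]) / od[PLATE_T0_MIN]
                fcs.append(raw - water_fc[rep])
            assert profile.loc[strain, substrate] == pytest.approx(
                np.mean(fcs), abs=1e-12)


def test_kmeans_recovers_planted_groups():
    strains = [f"s{i}" for i in range(6)]
    usage, truth = synth.make_substrate_cluster_usage(strains)
    profile = fold_change(synth.make_plate(usage, noise_sd=0.1, seed=4))
    labels = substrate_kmeans(profile, k=2, restarts=100, seed=0)
    assert adjusted_rand_score(truth[labels.index], labels.values) >= 0.9
    # determinism
    again = substrate_kmeans(profile, k=2, restarts=100, seed=0)
    assert labels.equals(again)


def test_kmeans_singletons_and_sse_monotonicity():
    strains = [f"s{i}" for i in range(4)]
    usage, _ = synth.make_substrate_cluster_usage(strains, n_per_group=3)
    profile = fold_change(synth.make_plate(usage, noise_sd=0.2, seed=2))
    k = profile.shape[1]
    labels = substrate_kmeans(profile, k=k, restarts=5, seed=0)
    assert labels.nunique() == k  # singleton clusters, SSE 0
    from sklearn.cluster import KMeans

    X = profile.T.to_numpy()
    sse = [KMeans(n_clusters=3, n_init=r, random_state=0).fit(X).inertia_
           for r in (1, 10, 50)]
    assert sse[0] >= sse[1] >= sse[2]


def test_strain_dendrogram_planted_groups():
    strains = [f"s{i}" for i in range(8)]
    usage, _ = synth.make_substrate_cluster_usage(strains, n_per_group=8)
    profile = fold_change(synth.make_plate(usage, noise_sd=0.15, seed=5))
    dend = strain_dendrogram(profile, n_boot=100, seed=0)
    left = set(strains[:4])
    right = set(strains[4:])
    assert dend.support_for(left) >= 0.9
    assert dend.support_for(right) >= 0.9


def test_strain_dendrogram_duplicates_and_no_boot():
    profile = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 0.0]],
                           index=["a", "b", "c"], columns=["s1", "s2"])
    dend = strain_dendrogram(profile, n_boot=0)
    assert dend.supports == {}
    assert dend.linkage_matrix[0, 2] == pytest.approx(0.0)


def test_model_agreement_counts_and_symmetry():
    calls = pd.DataFrame(
        [[True, True, False, False, True], [True, False, True, False, True]],
        index=["s1", "s2"], columns=list("abcde"))
    preds = pd.DataFrame(
        [[True, False, False, True, True], [True, False, True, True, True]],
        index=["s1", "s2"], columns=list("abcde"))
    per_strain, overall = model_agreement(calls, preds)
    assert overall == pytest.approx(0.7)  # 7 of 10 cells agree
    assert model_agreement(preds, calls)[1] == pytest.approx(overall)
    assert model_agreement(calls, calls)[1] == pytest.approx(1.0)


def test_model_agreement_requires_shared_universe():
    a = pd.DataFrame([[True]], index=["s1"], columns=["x"])
    b = pd.DataFrame([[True]], index=["s1"], columns=["y"])
    with pytest.raises(ValueError, match="shared"):
        model_agreement(a, b)


def test_binarized_calls_recover_planted_usage():
    strains = [f"s{i}" for i in range(4)]
    usage, _ = synth.make_substrate_cluster_usage(strains, n_per_group=4)
    profile = fold_change(synth.make_plate(usage, noise_sd=0.0, seed=0))
    calls = binarize_profile(profile)
    assert calls.equals(usage.reindex(calls.index)[calls.columns])
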