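"""BIOLOG GN2 phenotype-microarray analysis.

Substrate reduction is scored as the fold change of tetrazolium absorbance
between inoculation and 46 h, with the water well's fold change subtracted
as background and the three replicates averaged.  Downstream: k-means of
substrates on their across-strain fold-change vectors, Ward dendrograms of
strains with bootstrap support, binary usage calls, and agreement with
model-predicted carbon-source usage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

from .diversity import Dendrogram
from .model_io import PLATE_T0_MIN, PLATE_T46_MIN, WATER_WELL, ParseError

logger = logging.getLogger("repertoire")

#: fold-change threshold for calling a substrate used (binarization)
FC_POSITIVE = 1.0


def fold_change(plate: pd.DataFrame) -> pd.DataFrame:
    """Strain x substrate fold-change profile.

    Per replicate: ``FC_raw = (OD_t46 - OD_t0) / OD_t0``; the water well's
    raw fold change is subtracted as background, then replicates are
    averaged.  The water well itself is excluded from the profile.
    ``OD_t0 = 0`` or a missing endpoint is an error.
    """
    for col in ("strain", "substrate", "replicate", "time_min", "od"):
        if col not in plate.columns:
            raise ParseError(f"plate table missing column {col!r}")
    ends = plate[plate["time_min"].isin([PLATE_T0_MIN, PLATE_T46_MIN])]
    wide = ends.pivot_table(
        index=["strain", "substrate", "replicate"], columns="time_min",
        values="od", aggfunc="first",
    )
    if PLATE_T0_MIN not in wide.columns or PLATE_T46_MIN not in wide.columns:
        raise ParseError("plate table lacks t0 and/or 46 h timepoints")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index[0]
        raise ParseError(f"well {missing} missing an endpoint timepoint")
    od0 = wide[PLATE_T0_MIN]
    if (od0 == 0).any():
        bad = od0[od0 == 0].index[0]
        raise ParseError(f"well {bad}: OD at t0 is zero (fold change undefined)")
    fc_raw = (wide[PLATE_T46_MIN] - od0) / od0
    fc = fc_raw.reset_index(name="fc")
    water = fc[fc["substrate"] == WATER_WELL].set_index(["strain", "replicate"])["fc"]
    if water.empty:
        raise ParseError(f"plate table lacks the {WATER_WELL!r} control well")
    fc = fc[fc["substrate"] != WATER_WELL].copy()
    fc["fc"] -= water.reindex(
        pd.MultiIndex.from_frame(fc[["strain", "replicate"]])
    ).to_numpy()
    profile = fc.pivot_table(index="strain", columns="substrate", values="fc",
                             aggfunc="mean")
    if profile.isna().any().any():
        raise ParseError("plate table has strain/substrate holes")
    return profile.sort_index().reindex(sorted(profile.columns), axis=1)


def binarize_profile(profile: pd.DataFrame, threshold: float = FC_POSITIVE) -> pd.DataFrame:
    """Boolean usage calls: fold change >= threshold."""
    return profile >= threshold


def substrate_kmeans(
    profile: pd.DataFrame,
    k: int = 7,
    restarts: int = 1000,
    seed: int | None = None,
) -> pd.Series:
    """Cluster substrates on their across-strain fold-change vectors.

    Best of ``restarts`` seeded initializations by within-cluster SSE;
    deterministic for a fixed seed.
    """
    if profile.shape[1] < k:
        raise ValueError(
            f"need at least k={k} substrates, got {profile.shape[1]}")
    X = profile.T.to_numpy(dtype=float)  # substrates x strains
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    return pd.Series(labels, index=profile.columns, name="cluster")


def strain_dendrogram(
    profile: pd.DataFrame, n_boot: int = 100, seed: int | None = None
) -> Dendrogram:
    """Ward clustering of strains on Euclidean fold-change distances, with
    bootstrap (over substrates) clade support."""
    if len(profile) < 3:
        raise ValueError("need at least 3 strains")
    ids = list(profile.index)
    X = profile.to_numpy(dtype=float)
    dend = Dendrogram(ids=ids, linkage_matrix=linkage(X, method="ward"))
    if n_boot <= 0:
        return dend
    clades = dend.clades()
    counts = dict.fromkeys(clades, 0)
    rng = np.random.default_rng(seed)
    n_col = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_col, size=n_col)
        Zb = linkage(X[:, cols], method="ward")
        boot = set(Dendrogram(ids=ids, linkage_matrix=Zb).clades())
        for clade in clades:
            if clade in boot:
                counts[clade] += 1
    dend.supports = {c: counts[c] / n_boot for c in clades}
    return dend


def model_agreement(
    binary_calls: pd.DataFrame, predictions: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Fraction of agreeing cells, (TP + TN) / total, per strain and overall.

    Substrates absent from either table are dropped (logged); the metric is
    symmetric in its two boolean arguments.
    """
    shared_cols = sorted(set(binary_calls.columns) & set(predictions.columns))
    shared_rows = sorted(set(binary_calls.index) & set(predictions.index))
    dropped = (set(binary_calls.columns) | set(predictions.columns)) - set(shared_cols)
    if dropped:
        logger.info("model_agreement: dropping unshared substrates %s",
                    sorted(dropped))
    if not shared_cols or not shared_rows:
        raise ValueError("no shared strain/substrate universe to compare")
    a = binary_calls.loc[shared_rows, shared_cols].astype(bool)
    b = predictions.loc[shared_rows, shared_cols].astype(bool)
    agree = a == b
    return agree.mean(axis=1), float(agree.to_numpy().mean())
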