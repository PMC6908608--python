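"""Phylogenetic vs metabolic similarity and bootstrapped clustering.

16S similarity is global-alignment percent identity; metabolic similarity
treats each isolate's pathway presence/absence profile as a binary vector
(Euclidean distance for clustering, simple matching coefficient as the
"metabolic identity" analogue of percent identity).  The two similarity
structures are compared with a Spearman correlation over pairwise values and
a Mantel-style permutation test; hierarchical clustering support comes from
a plain bootstrap over pathway columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

# global pairwise-alignment scoring for 16S identity
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -2.0, -0.5


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, identity scale [0, 1]

    def validate(self) -> "SimilarityMatrix":
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("similarity matrix diagonal must be 1")
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


@dataclass
class Dendrogram:
    ids: list[str]
    linkage_matrix: np.ndarray
    supports: dict[frozenset, float] = field(default_factory=dict)

    def clades(self) -> list[frozenset]:
        """Leaf-id sets of all internal nodes."""
        tree = to_tree(self.linkage_matrix)
        out = []

        def walk(node):
            if node.is_leaf():
                return frozenset([self.ids[node.id]])
            leaves = walk(node.left) | walk(node.right)
            out.append(leaves)
            return leaves

        walk(tree)
        return out

    def support_for(self, leaf_ids: set[str]) -> float | None:
        return self.supports.get(frozenset(leaf_ids))

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            leaves = frozenset(_leaf_ids(node, self.ids))
            label = ""
            if leaves in self.supports:
                label = f"{self.supports[leaves]:.2f}"
            return f"({left},{right}){label}:{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _leaf_ids(node, ids):
    if node.is_leaf():
        return [ids[node.id]]
    return _leaf_ids(node.left, ids) + _leaf_ids(node.right, ids)


# ---------------------------------------------------------------------------
# 16S identity
# ---------------------------------------------------------------------------

def pairwise_identity_16s(
    sequences: dict[str, str], denominator: str = "columns"
) -> SimilarityMatrix:
    """Percent identity from global pairwise alignments.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -0.5.  Identity
    defaults to matches over all alignment columns (gaps included);
    ``denominator='aligned'`` uses only non-gap columns.
    """
    from Bio import Align

    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {sid!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    ids = list(sequences)
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(sequences[ids[i]], sequences[ids[j]])[0]
            counts = aln.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            denom = columns if denominator == "columns" else (
                counts.identities + counts.mismatches)
            mat[i, j] = mat[j, i] = counts.identities / denom if denom else 0.0
    return SimilarityMatrix(ids=ids, values=mat).validate()


# ---------------------------------------------------------------------------
# Metabolic vectors and distances
# ---------------------------------------------------------------------------

def metabolic_vectors(calls_or_matrix) -> pd.DataFrame:
    """Isolate x pathway binary matrix with a fixed (sorted) pathway order.

    Accepts either a list of :class:`~repertoire.pathways.PresenceCall` or a
    boolean DataFrame.
    """
    if isinstance(calls_or_matrix, pd.DataFrame):
        df = calls_or_matrix.copy()
    else:
        from .pathways import presence_matrix
        df = presence_matrix(calls_or_matrix)
    return df.reindex(sorted(df.columns), axis=1).astype(int)


def metabolic_similarity(
    vectors: pd.DataFrame,
) -> tuple[SimilarityMatrix, pd.DataFrame]:
    """Simple-matching similarity (fraction of agreeing presence/absence
    calls) and the Euclidean distance matrix over pathway vectors."""
    X = vectors.to_numpy(dtype=float)
    ids = list(vectors.index)
    dist = squareform(pdist(X, metric="euclidean"))
    n_col = X.shape[1]
    if n_col == 0:
        raise ValueError("no pathway columns")
    ham = squareform(pdist(X, metric="hamming")) if n_col else np.zeros_like(dist)
    sim = SimilarityMatrix(ids=ids, values=1.0 - ham).validate()
    return sim, pd.DataFrame(dist, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Mantel-style correlation
# ---------------------------------------------------------------------------

def correlate_matrices(
    a: SimilarityMatrix,
    b: SimilarityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rho over upper-triangle pairs, with a Mantel permutation p.

    The null permutes rows and columns of ``b`` simultaneously (preserving
    the within-matrix dependence structure that makes pairwise values
    non-exchangeable); p = (1 + #{|rho_perm| >= |rho|}) / (n_perm + 1),
    two-sided.
    """
    if a.ids != b.ids:
        raise ValueError("matrices must share the same ids in the same order")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a.validate(), b.validate()
    n = len(a.ids)
    iu = np.triu_indices(n, k=1)
    au, bu = a.values[iu], b.values[iu]
    rho = spearmanr(au, bu).statistic
    rng = np.random.default_rng(seed)
    ra = rankdata(au)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        bp = b.values[np.ix_(p, p)][iu]
        rp = np.corrcoef(ra, rankdata(bp))[0, 1]
        if abs(rp) >= abs(rho) - 1e-12:
            hits += 1
    return float(rho), (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Bootstrapped hierarchical clustering
# ---------------------------------------------------------------------------

def cluster_with_bootstrap(
    vectors: pd.DataFrame,
    n_boot: int = 1000,
    method: str = "average",
    seed: int | None = None,
) -> Dendrogram:
    """Hierarchical clustering of pathway vectors (Euclidean distance) with
    bootstrap clade support.

    Support for an internal node is the fraction of ``n_boot`` column
    resamples whose tree contains the same leaf set; ``n_boot = 0`` returns
    the tree without supports.
    """
    if len(vectors) < 3:
        raise ValueError("need at least 3 isolates to cluster")
    ids = list(vectors.index)
    X = vectors.to_numpy(dtype=float)
    Z = linkage(X, method=method, metric="euclidean")
    dend = Dendrogram(ids=ids, linkage_matrix=Z)
    if n_boot <= 0:
        return dend
    clades = dend.clades()
    counts = dict.fromkeys(clades, 0)
    rng = np.random.default_rng(seed)
    n_col = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_col, size=n_col)
        Zb = linkage(X[:, cols], method=method, metric="euclidean")
        boot_clades = set(Dendrogram(ids=ids, linkage_matrix=Zb).clades())
        for clade in clades:
            if clade in boot_clades:
                counts[clade] += 1
    dend.supports = {c: counts[c] / n_boot for c in clades}
    return dend
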