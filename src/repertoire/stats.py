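"""Trait-phenotype association statistics.

Per binary metabolic trait: Spearman correlation with the phenotype, an
empirical permutation p-value against randomly generated features
(prevalence-preserving column permutations by default), and
Benjamini-Hochberg FDR adjustment across traits.  Also a Wilcoxon rank-sum
utility (exact enumeration for small samples, normal approximation with tie
correction otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, spearmanr

logger = logging.getLogger("repertoire")

EXACT_MAX_N = 20  # exact Wilcoxon enumeration up to this combined sample size


@dataclass
class AssociationResult:
    trait_id: str
    rho: float
    p_perm: float
    q: float


def benjamini_hochberg(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment: q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _spearman_rho(rank_t: np.ndarray, rank_p: np.ndarray) -> float:
    rt = rank_t - rank_t.mean()
    rp = rank_p - rank_p.mean()
    denom = np.sqrt((rt ** 2).sum() * (rp ** 2).sum())
    return float((rt * rp).sum() / denom) if denom > 0 else np.nan


def spearman_perm(
    traits: pd.DataFrame,
    phenotype: pd.Series,
    n_random: int = 100,
    seed: int | None = None,
    null_mode: str = "permute",
) -> list[AssociationResult]:
    """Association of each binary trait with a numeric phenotype.

    The null for each trait is ``n_random`` randomly generated features:
    prevalence-preserving permutations of the trait column (default) or
    Bernoulli draws with matched prevalence (``null_mode='bernoulli'``).
    ``p = (1 + #{|rho_null| >= |rho|}) / (n_random + 1)`` (add-one rule, so p
    is never 0); q is Benjamini-Hochberg across traits.  Constant trait
    columns are dropped with a log message; a constant phenotype is an
    error.  p is invariant to monotone transforms of the phenotype (ranks
    only are used).
    """
    if null_mode not in ("permute", "bernoulli"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    traits = traits.loc[phenotype.index]
    y = phenotype.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; correlation undefined")
    keep = [c for c in traits.columns if traits[c].nunique() > 1]
    dropped = [c for c in traits.columns if c not in keep]
    if dropped:
        logger.info("spearman_perm: dropping constant trait columns %s", dropped)
    rank_y = rankdata(y)
    rng = np.random.default_rng(seed)
    n = len(y)
    rhos, pvals = [], []
    for trait in keep:
        t = traits[trait].to_numpy(dtype=float)
        rho = _spearman_rho(rankdata(t), rank_y)
        if null_mode == "permute":
            null_cols = rng.permuted(
                np.tile(t, (n_random, 1)), axis=1)
        else:
            prev = t.mean()
            null_cols = (rng.random((n_random, n)) < prev).astype(float)
        null_rhos = np.array([
            _spearman_rho(rankdata(col), rank_y) for col in null_cols
        ])
        null_rhos = null_rhos[~np.isnan(null_rhos)]
        hits = int((np.abs(null_rhos) >= abs(rho) - 1e-12).sum())
        pvals.append((1 + hits) / (n_random + 1))
        rhos.append(rho)
    qvals = benjamini_hochberg(pvals)
    return [
        AssociationResult(trait_id=t, rho=r, p_perm=p, q=q)
        for t, r, p, q in zip(keep, rhos, pvals, qvals)
    ]


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"trait_id": r.trait_id, "rho": r.rho, "p_perm": r.p_perm, "q": r.q}
         for r in results]
    )
    return df.reindex(df["rho"].abs().sort_values(ascending=False).index)


def wilcoxon_rank_sum(
    x, y, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``mode='exact'`` enumerates the null (valid without ties), ``'normal'``
    uses the tie-corrected normal approximation, ``'auto'`` picks exact for
    combined n <= 20 without ties.  Returns ``(U statistic of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= EXACT_MAX_N and not has_ties) \
            else "normal"
    if mode == "exact" and has_ties:
        logger.info("wilcoxon_rank_sum: ties present; using normal approximation")
        mode = "normal"
    method = {"exact": "exact", "normal": "asymptotic"}[mode]
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Plain Spearman rho and asymptotic p (NaN, NaN when degenerate)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
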