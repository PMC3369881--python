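"""Enrichment and bias statistics for gene clusters.

Three families of tests, matching how co-expression cohorts are profiled
against external gene data:

* categorical data — cumulative hypergeometric tests ("at least k cluster
  genes among the n genes of a category") with the enrichment ratio
  E = (k/m)/(n/N);
* numerical data — two-sided Mann-Whitney-Wilcoxon tests with the
  normalized rank-sum statistic r = 2U/(mn) - 1 in [-1, 1] (direction and
  extent of the bias), or Welch's t-test for normally distributed data;
* compendium meta-analysis — normalized rank sums of a cluster's genes
  within each of many unrelated expression experiments, SOTA-style
  clustering of the experiments, and Spearman correlation of cluster
  profiles.

GO-style annotations are used as flat term -> gene sets; terms are *not*
propagated along the ontology graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class HypergeomResult:
    """One (cluster, category) enrichment cell.

    N genes in the universe, m in the cluster, n in the category, k in the
    overlap; p = P(X >= k) under the hypergeometric null; E = (k/m)/(n/N).
    """

    N: int
    m: int
    n: int
    k: int
    p: float
    E: float


@dataclass
class RankBiasResult:
    U: float        # Mann-Whitney statistic: cluster-over-rest pairs, ties 1/2
    r: float        # 2U/(mn) - 1
    u_frac: float   # U/(mn)
    p: float        # two-sided


def hypergeom_enrichment(cluster, category, universe) -> HypergeomResult:
    """Cumulative hypergeometric enrichment of a category in a cluster."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    cluster = set(cluster) & universe
    category = set(category) & universe
    N, m, n = len(universe), len(cluster), len(category)
    k = len(cluster & category)
    p = float(stats.hypergeom.sf(k - 1, N, n, m)) if k > 0 else 1.0
    E = (k / m) / (n / N) if m > 0 and n > 0 else 0.0
    return HypergeomResult(N=N, m=m, n=n, k=k, p=min(p, 1.0), E=E)


def enrich_categories(
    labels: pd.Series,
    categories: dict,
    universe=None,
    p_report: float = 1e-4,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric tests for every (cluster, category) pair.

    ``categories`` is a flat term -> gene-set mapping (GMT-style; no
    ontology propagation).  The full table is returned with a boolean
    ``significant`` column at the display cutoff ``p_report``; raw p-values
    are reported by default, with an optional Benjamini-Hochberg column.
    """
    if universe is None:
        universe = labels.index
    universe = pd.Index(universe)
    rows = []
    for term, genes in categories.items():
        genes = set(genes)
        if not (genes & set(universe)):
            warnings.warn(f"category {term!r} is disjoint from the universe; skipped")
            continue
        for cl in sorted(labels.unique()):
            members = labels.index[labels == cl]
            res = hypergeom_enrichment(members, genes, universe)
            rows.append(dict(cluster=cl, category=term, N=res.N, m=res.m,
                             n=res.n, k=res.k, E=res.E, p=res.p))
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p"] <= p_report
    return out.sort_values("p", ignore_index=True)


def _mww_u(cluster_values: np.ndarray, rest_values: np.ndarray) -> float:
    """U = number of (cluster, rest) pairs with cluster > rest, ties as 1/2."""
    pooled = np.concatenate([cluster_values, rest_values])
    ranks = stats.rankdata(pooled)
    m = cluster_values.size
    return float(ranks[:m].sum() - m * (m + 1) / 2)


def ranksum_bias(cluster_values, rest_values, exact_threshold: int = 50) -> RankBiasResult:
    """Two-sided Mann-Whitney-Wilcoxon bias test with the normalized statistic.

    r = 2U/(mn) - 1 is +1 when every cluster value exceeds every rest value,
    -1 in the opposite case, and 0 in expectation under exchangeability.
    The p-value is exact (network/shift enumeration) for m+n up to
    ``exact_threshold`` without ties, and the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(cluster_values, dtype=float)
    y = np.asarray(rest_values, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    m, n = x.size, y.size
    if m < 1 or n < 1:
        raise ValueError("both groups must be non-empty")
    U = _mww_u(x, y)
    r = 2 * U / (m * n) - 1
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return RankBiasResult(U=U, r=0.0, u_frac=0.5, p=1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (m + n <= exact_threshold and not has_ties) else "asymptotic"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return RankBiasResult(U=U, r=r, u_frac=U / (m * n), p=min(p, 1.0))


def welch_bias(cluster_values, rest_values) -> tuple[float, float, float]:
    """Welch's t-test of cluster vs rest: (t, Satterthwaite dof, two-sided p).

    t > 0 indicates higher values in the cluster than in the rest.
    """
    x = np.asarray(cluster_values, dtype=float)
    y = np.asarray(rest_values, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch test needs at least 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    tol = 1e-12 * max(1.0, float(np.max(np.abs(np.concatenate([x, y])))))
    if np.sqrt(vx) <= tol and np.sqrt(vy) <= tol:
        if abs(x.mean() - y.mean()) <= tol:
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    dof = (sx + sy) ** 2 / (sx ** 2 / (x.size - 1) + sy ** 2 / (y.size - 1))
    p = 2 * stats.t.sf(abs(t), dof)
    return float(t), float(dof), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# compendium meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaRankProfile:
    r_tilde: pd.DataFrame      # cluster x experiment, 2U/(mn)-1
    u_frac: pd.DataFrame       # cluster x experiment, U/(mn)
    pvalues: pd.DataFrame
    experiment_clusters: pd.Series | None = None
    column_order: list | None = None


def meta_rank_sums(compendium: pd.DataFrame, labels: pd.Series,
                   clusters=None) -> MetaRankProfile:
    """Normalized rank sums of each cluster across a compendium of experiments.

    Per (cluster, experiment): the cluster genes' values in that experiment
    versus all other genes' values, with pairwise exclusion of missing
    values.  r_tilde > 0 signals a bias of the cluster genes towards
    upregulation in the experiment, r_tilde < 0 towards downregulation.
    """
    if clusters is None:
        clusters = sorted(labels.unique())
    genes = compendium.index.intersection(labels.index)
    comp = compendium.loc[genes]
    labs = labels.loc[genes]
    r = pd.DataFrame(0.0, index=clusters, columns=comp.columns)
    uf = pd.DataFrame(0.5, index=clusters, columns=comp.columns)
    pv = pd.DataFrame(1.0, index=clusters, columns=comp.columns)
    for exp in comp.columns:
        col = comp[exp].dropna()
        if np.unique(col).size < 2:
            continue
        in_cluster = {cl: col[labs.loc[col.index] == cl] for cl in clusters}
        for cl in clusters:
            xs = in_cluster[cl]
            ys = col.drop(xs.index)
            if len(xs) == 0 or len(ys) == 0:
                continue
            res = ranksum_bias(xs.to_numpy(), ys.to_numpy())
            r.loc[cl, exp] = res.r
            uf.loc[cl, exp] = res.u_frac
            pv.loc[cl, exp] = res.p
    return MetaRankProfile(r_tilde=r, u_frac=uf, pvalues=pv)


def _sota_refine(points: np.ndarray, members: np.ndarray, c1: np.ndarray,
                 c2: np.ndarray, rng, lr_winner=0.1, lr_sibling=0.01,
                 epochs: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Winner-take-most training of a freshly split pair of centroid cells."""
    c1, c2 = c1.copy(), c2.copy()
    prev = np.inf
    for _ in range(epochs):
        order = rng.permutation(members)
        for i in order:
            x = points[i]
            d1 = np.sum((x - c1) ** 2)
            d2 = np.sum((x - c2) ** 2)
            if d1 <= d2:
                c1 += lr_winner * (x - c1)
                c2 += lr_sibling * (x - c2)
            else:
                c2 += lr_winner * (x - c2)
                c1 += lr_sibling * (x - c1)
        err = sum(min(np.sum((points[i] - c1) ** 2), np.sum((points[i] - c2) ** 2))
                  for i in members)
        if prev - err < 1e-6 * max(prev, 1e-12):
            break
        prev = err
    return c1, c2


def cluster_experiments(profiles: pd.DataFrame, K: int = 5, seed: int = 0,
                        anchor=None) -> tuple[pd.Series, list]:
    """SOTA-style divisive clustering of experiments by their rank-sum profiles.

    Experiments (columns of the cluster x experiment profile matrix) are
    grown into a binary tree of centroid cells: the cell with the largest
    mean within-cell distance (its "resource") is split, the two children
    are trained with winner-take-most updates, until K cells exist.
    Experiment-clusters and the experiments within them are then ordered by
    decreasing mean of the anchor cluster's (default: first row's) r values.

    Returns (experiment -> cluster id Series, ordered experiment list).
    """
    if not np.all(np.isfinite(profiles.to_numpy())):
        raise ValueError("profile matrix must be finite")
    n_exp = profiles.shape[1]
    if K > n_exp:
        raise ValueError(f"K={K} exceeds the number of experiments ({n_exp})")
    if anchor is None:
        anchor = profiles.index[0]
    rng = np.random.default_rng(seed)
    points = profiles.to_numpy(dtype=float).T        # experiments as rows
    centroids = [points.mean(axis=0)]
    while len(centroids) < K:
        cmat = np.asarray(centroids)
        assign = np.argmin(((points[:, None, :] - cmat[None]) ** 2).sum(-1), axis=1)
        resource = np.full(len(centroids), -1.0)
        for c in range(len(centroids)):
            mem = np.flatnonzero(assign == c)
            if mem.size:
                resource[c] = np.mean(np.sum((points[mem] - cmat[c]) ** 2, axis=1))
        split = int(np.argmax(resource))
        members = np.flatnonzero(assign == split)
        if members.size >= 2:
            d = np.sum((points[members] - cmat[split]) ** 2, axis=1)
            far = points[members[np.argmax(d)]]
            c1, c2 = cmat[split], far.copy()
        else:
            eps = 1e-6 * (1 + np.abs(cmat[split]))
            c1, c2 = cmat[split] - eps, cmat[split] + eps
        c1, c2 = _sota_refine(points, members, c1, c2, rng)
        centroids[split] = c1
        centroids.append(c2)
    cmat = np.asarray(centroids)
    assign = np.argmin(((points[:, None, :] - cmat[None]) ** 2).sum(-1), axis=1)
    exp_clusters = pd.Series(assign, index=profiles.columns)

    anchor_vals = profiles.loc[anchor]
    cl_mean = anchor_vals.groupby(exp_clusters).mean().sort_values(ascending=False)
    order = []
    relabel = {}
    for rank, c in enumerate(cl_mean.index, start=1):
        relabel[c] = rank
        cols = anchor_vals[exp_clusters == c].sort_values(ascending=False).index
        order.extend(cols)
    return exp_clusters.map(relabel), order


def profile_correlation(profile_i, profile_j) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) between two r-tilde profiles."""
    x = np.asarray(profile_i, dtype=float)
    y = np.asarray(profile_j, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant profile: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
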