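"""Weighted co-expression modules, per-tissue activity (NES) and hub genes.

The module detector follows the classic weighted-network recipe: soft-power
adjacency |r|^beta on Pearson correlations across samples, topological
overlap dissimilarity, average-linkage hierarchical clustering, and a static
tree cut (default height 0.995). Clusters of at least ``min_module_size``
genes become modules M1, M2, ... by descending size; everything else lands
in an unassigned bin. The procedure is deterministic and invariant to gene
order.

Module activity per tissue is a permutation-normalized enrichment score:
the observed statistic is the mean gene-standardized log2 TPM of the module
genes over the tissue's samples, the null is the same statistic for random
gene sets of equal size, NES = (obs - null mean) / null sd, and the p-value
is the upper-tail permutation probability with +1 smoothing. Random *gene
sets* (not sample labels) form the null because two replicates per tissue
are far too few to permute.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .atlas import ExpressionAtlas

logger = logging.getLogger(__name__)

__all__ = [
    "CoexprModule",
    "select_genes",
    "select_soft_power",
    "adjacency_matrix",
    "detect_modules",
    "module_activity",
    "find_hubs",
]


@dataclass
class CoexprModule:
    """A detected co-expression module.

    ``activity`` maps tissue -> (nes, p); ``hubs`` is a ranked list of
    (gene, intramodule connectivity) pairs.
    """

    id: str
    genes: list
    activity: dict = field(default_factory=dict)
    hubs: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


def select_genes(profile_or_expr: pd.DataFrame, n_top: int) -> list:
    """Top ``n_top`` genes by variance of log2(TPM+1) across columns."""
    if n_top > profile_or_expr.shape[0]:
        raise ValueError("n_top exceeds the number of genes")
    logx = np.log2(profile_or_expr.values.astype(float) + 1.0)
    var = logx.var(axis=1, ddof=1)
    order = np.lexsort((profile_or_expr.index.to_numpy(), -var))
    return sorted(profile_or_expr.index.to_numpy()[order[:n_top]])


def _scale_free_r2(k: np.ndarray, nbins: int = 10) -> float:
    """Signed scale-free fit of the degree distribution.

    Bins the connectivities, regresses log10 frequency on log10 mean
    connectivity and returns R^2 when the slope is negative (a decreasing
    degree distribution, the scale-free signature) and -R^2 otherwise, the
    convention of weighted co-expression network analysis.
    """
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) < 1e-12:
        return np.nan
    edges = np.linspace(k.min(), k.max() + 1e-9, nbins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(nbins):
        kb = k[which == b]
        if kb.size:
            xs.append(np.log10(kb.mean()))
            ys.append(np.log10(kb.size / k.size))
    if len(xs) < 2:
        return np.nan
    x, y = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot <= 0:
        return np.nan
    r2 = float(1.0 - (resid**2).sum() / ss_tot)
    return r2 if slope < 0 else -r2


def _conventional_power(n_samples: int) -> int:
    """Fixed unsigned-network soft power by sample count (the WGCNA ladder)."""
    if n_samples < 20:
        return 10
    if n_samples < 30:
        return 9
    if n_samples < 40:
        return 8
    return 7


def select_soft_power(corr: np.ndarray, candidates=range(1, 21),
                      r2_target: float = 0.8, fallback: int = 6,
                      n_samples: int | None = None) -> int:
    """Smallest soft power whose network is approximately scale-free.

    Picks the smallest beta with signed scale-free fit R^2 >= ``r2_target``.
    When no candidate qualifies (block-structured or degenerate correlation
    matrices never fit a power law well) a fixed conventional power is used
    with a warning: the sample-count ladder when ``n_samples`` is given,
    otherwise ``fallback``. Deterministic.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    for beta in candidates:
        A = np.abs(corr) ** beta
        np.fill_diagonal(A, 0.0)
        r2 = _scale_free_r2(A.sum(axis=1))
        if np.isfinite(r2) and r2 >= r2_target:
            return int(beta)
    chosen = _conventional_power(n_samples) if n_samples is not None else fallback
    logger.warning(
        "no soft power reached scale-free R^2 >= %.2f; using beta=%d",
        r2_target, chosen,
    )
    return int(chosen)


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Soft-power adjacency |Pearson r|^beta of a samples x genes matrix."""
    X = expr.values.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X.T)
    r = np.nan_to_num(r, nan=0.0)
    A = np.abs(r) ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=expr.columns, columns=expr.columns)


def _tom_dissimilarity(A: np.ndarray) -> np.ndarray:
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def detect_modules(
    expr: pd.DataFrame,
    beta: int,
    min_module_size: int = 10,
    cut_height: float = 0.995,
    prune_frac: float = 0.1,
) -> tuple:
    """Detect co-expression modules in a samples x genes log2 matrix.

    After the static tree cut, each candidate cluster is pruned of weakly
    attached genes: a member whose mean adjacency to the rest of the cluster
    falls below ``prune_frac`` times the cluster median is dropped (the
    module-membership cleanup standard in weighted co-expression analysis;
    chance correlations otherwise glue unrelated genes to a strong module).

    Returns ``(modules, adjacency)`` where modules is a list of
    :class:`CoexprModule` labelled M1... by descending size and adjacency is
    the genes x genes soft-power matrix (needed for hub ranking). Finding no
    module of the minimum size is a valid empty result.
    """
    adj = adjacency_matrix(expr, beta)
    diss = _tom_dissimilarity(adj.values)
    # clip tiny negatives from floating error
    condensed = np.maximum(squareform(diss, checks=False), 0.0)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    genes = adj.index.to_numpy()
    clusters = []
    for lab in np.unique(labels):
        members = sorted(genes[labels == lab])
        if len(members) < min_module_size:
            continue
        if prune_frac > 0:
            sub = adj.loc[members, members].values
            mean_adj = sub.sum(axis=1) / (len(members) - 1)
            keep = mean_adj >= prune_frac * np.median(mean_adj)
            members = [g for g, k in zip(members, keep) if k]
        if len(members) >= min_module_size:
            clusters.append(members)
    clusters.sort(key=lambda m: (-len(m), m[0]))
    modules = [CoexprModule(id=f"M{i + 1}", genes=m) for i, m in enumerate(clusters)]
    return modules, adj


def module_activity(
    module_genes,
    atlas: ExpressionAtlas,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation NES of a gene set in every tissue of the atlas.

    Returns tissue -> (nes, p) with a one-sided (upper tail) permutation
    p-value smoothed by +1 in numerator and denominator.
    """
    genes = list(module_genes)
    universe = atlas.expression.index
    idx = universe.get_indexer(genes)
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise ValueError(f"module genes absent from atlas: {missing[:5]}")
    if len(genes) >= len(universe):
        raise ValueError("module is as large as the gene universe")

    logx = np.log2(atlas.expression.values.astype(float) + 1.0)
    mean = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, ddof=1, keepdims=True)
    # genes constant up to floating error carry no signal: z = 0
    informative = sd > 1e-9 * np.maximum(1.0, np.abs(mean))
    z = np.where(informative, (logx - mean) / np.where(informative, sd, 1.0), 0.0)

    tissues = atlas.tissues
    sample_pos = {s: i for i, s in enumerate(atlas.expression.columns)}
    # per-gene mean z within each tissue's samples
    zt = np.column_stack([
        z[:, [sample_pos[s] for s in atlas.samples_of(t)]].mean(axis=1)
        for t in tissues
    ])
    obs = zt[idx].mean(axis=0)

    rng = np.random.default_rng(seed)
    m = len(genes)
    perm = np.empty((n_perm, len(tissues)))
    for b in range(n_perm):
        rand_idx = rng.choice(len(universe), size=m, replace=False)
        perm[b] = zt[rand_idx].mean(axis=0)
    null_mean = perm.mean(axis=0)
    null_sd = perm.std(axis=0, ddof=1)
    nes = (obs - null_mean) / np.where(null_sd > 0, null_sd, 1.0)
    p = (1.0 + (perm >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    return {t: (float(nes[i]), float(p[i])) for i, t in enumerate(tissues)}


def find_hubs(module_genes, adjacency: pd.DataFrame, k: int = 5) -> list:
    """Top-k genes by intramodule connectivity (row sums of the adjacency
    restricted to the module), ties broken by gene id."""
    genes = list(module_genes)
    if k > len(genes):
        logger.warning("k=%d exceeds module size %d; returning all genes", k, len(genes))
        k = len(genes)
    sub = adjacency.loc[genes, genes].values
    conn = sub.sum(axis=1)
    order = sorted(range(len(genes)), key=lambda i: (-conn[i], genes[i]))
    return [(genes[i], float(conn[i])) for i in order[:k]]
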