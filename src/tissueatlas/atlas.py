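"""Expression atlas: replicate averaging, filtering, tau and gene classification.

The tissue-specificity index of a gene g over N tissues is

    tau = sum_i (1 - x_i / x_max) / (N - 1)

computed on arithmetic-mean TPM per tissue, where x_max is the gene's maximal
tissue mean. tau is 0 for a uniformly expressed gene and 1 for a gene expressed
in exactly one tissue. Genes are then placed into four mutually exclusive
categories, in precedence order:

TissueSpecific   tau > 0.85 and the top tissue mean is at least ``fold_specific``
                 (default 5) times the maximum of every other tissue mean.
GroupEnriched    tau > 0.5 and there is a smallest k in [2, 7] such that, with
                 tissue means sorted descending, the k-th mean is at least
                 5 times the (k+1)-th (enhanced expression confined to a
                 group of 2-7 tissues).
ExpressedInAll   mean >= detect_tpm (default 1 TPM) in every tissue.
Mixed            everything else that survived the detection filter.

The five-fold rule compares against the *maximum* of the other tissues, the
strictest reading of "higher expression compared to all other tissues" and the
one used by the Human Protein Atlas classification scheme.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CATEGORIES

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionAtlas",
    "average_replicates",
    "filter_genes",
    "compute_tau",
    "classify_genes",
    "tissue_correlation",
    "foldchange_tau_correlation",
]


@dataclass
class ExpressionAtlas:
    """A genes x samples TPM matrix plus the sample -> tissue design.

    ``expression`` is indexed by gene id with one column per sample;
    ``design`` has columns ``sample_id`` and ``tissue``.
    """

    expression: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if (self.expression.values < 0).any():
            raise ValueError("expression values must be non-negative")
        design_samples = set(self.design["sample_id"])
        missing = [s for s in self.expression.columns if s not in design_samples]
        if missing:
            raise ValueError(f"samples missing from design: {missing[:5]}")
        if self.design["tissue"].nunique() < 2:
            raise ValueError("need at least 2 tissues")

    @property
    def tissues(self) -> list:
        return sorted(self.design["tissue"].unique())

    def samples_of(self, tissue: str) -> list:
        d = self.design
        return list(d.loc[d["tissue"] == tissue, "sample_id"])


def average_replicates(atlas: ExpressionAtlas) -> pd.DataFrame:
    """Arithmetic-mean TPM per tissue; returns a genes x tissues profile.

    Tissue columns are sorted by name so downstream argmax tie-breaks are
    deterministic.
    """
    tissue_of = dict(zip(atlas.design["sample_id"], atlas.design["tissue"]))
    groups = atlas.expression.T.groupby(
        atlas.expression.columns.map(tissue_of.get)
    )
    empty = set(atlas.design["tissue"]) - set(groups.groups)
    if empty:
        raise ValueError(f"tissue with zero samples: {sorted(empty)}")
    profile = groups.mean().T
    return profile[sorted(profile.columns)]


def filter_genes(
    profile: pd.DataFrame,
    ncrna_ids=(),
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Drop genes with grand mean <= ``min_mean`` TPM and annotated ncRNAs.

    Removal at the threshold is inclusive: a gene whose mean over all tissues
    is exactly ``min_mean`` is removed. Raises if nothing survives.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    ncrna = set(ncrna_ids)
    grand_mean = profile.mean(axis=1)
    low = grand_mean <= min_mean
    is_nc = profile.index.isin(ncrna)
    keep = ~low & ~is_nc
    logger.info(
        "filter_genes: removed %d low-expression genes (mean <= %g TPM) and "
        "%d ncRNA genes; %d retained",
        int(low.sum()), min_mean, int((is_nc & ~low).sum()), int(keep.sum()),
    )
    if not keep.any():
        raise ValueError("filter removed every gene")
    return profile.loc[keep]


def compute_tau(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-gene tau, maximal tissue and maximal TPM from a tissue profile."""
    X = profile.values.astype(float)
    n_tissues = X.shape[1]
    if n_tissues < 2:
        raise ValueError("tau needs at least 2 tissues")
    xmax = X.max(axis=1)
    if (xmax <= 0).any():
        bad = list(profile.index[xmax <= 0][:5])
        raise ValueError(f"all-zero expression profile, tau undefined: {bad}")
    tau = (1.0 - X / xmax[:, None]).sum(axis=1) / (n_tissues - 1)
    # columns are name-sorted, so argmax resolves ties to the first tissue name
    argmax = X.argmax(axis=1)
    return pd.DataFrame(
        {
            "tau": tau,
            "max_tissue": np.asarray(profile.columns)[argmax],
            "max_tpm": xmax,
        },
        index=profile.index,
    )


def _sorted_profile(profile: pd.DataFrame):
    """Row-wise descending sort of tissue means, ties broken by tissue name."""
    X = profile.values.astype(float)
    names = np.asarray(profile.columns)
    # lexsort: primary key -value, secondary key tissue name
    order = np.lexsort((np.broadcast_to(np.arange(X.shape[1]), X.shape), -X), axis=1)
    sorted_vals = np.take_along_axis(X, order, axis=1)
    return sorted_vals, order, names


def classify_genes(
    profile: pd.DataFrame,
    tau_table: pd.DataFrame,
    detect_tpm: float = 1.0,
    tau_specific: float = 0.85,
    fold_specific: float = 5.0,
    tau_group: float = 0.5,
    group_max: int = 7,
) -> pd.DataFrame:
    """Assign each gene to one of the four categories (precedence order).

    Returns the tau table augmented with ``fold_over_rest`` (top tissue mean
    over the maximum of the other tissue means), ``category`` and ``group``
    (semicolon-joined tissues; the single target tissue for TissueSpecific).
    """
    if not profile.index.equals(tau_table.index):
        raise ValueError("profile and tau table cover different gene sets")
    X = profile.values.astype(float)
    n_genes, n_tissues = X.shape
    sorted_vals, order, names = _sorted_profile(profile)
    top = sorted_vals[:, 0]
    second = sorted_vals[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_over_rest = np.where(second > 0, top / np.where(second > 0, second, 1.0), np.inf)
    tau = tau_table["tau"].values

    is_ts = (tau > tau_specific) & (top >= fold_specific * second)

    # smallest k in [2, group_max] with min(top-k) >= fold * max(rest)
    kmax = min(group_max, n_tissues - 1)
    group_k = np.zeros(n_genes, dtype=int)
    for k in range(2, kmax + 1):
        ok = (sorted_vals[:, k - 1] >= fold_specific * sorted_vals[:, k]) & (group_k == 0)
        group_k[ok] = k
    is_ge = (tau > tau_group) & (group_k > 0) & ~is_ts

    is_all = (X >= detect_tpm).all(axis=1) & ~is_ts & ~is_ge

    category = np.full(n_genes, "Mixed", dtype=object)
    category[is_all] = "ExpressedInAll"
    category[is_ge] = "GroupEnriched"
    category[is_ts] = "TissueSpecific"

    group = np.full(n_genes, "", dtype=object)
    ts_idx = np.flatnonzero(is_ts)
    group[ts_idx] = tau_table["max_tissue"].values[ts_idx]
    for i in np.flatnonzero(is_ge):
        members = names[order[i, : group_k[i]]]
        group[i] = ";".join(sorted(members))

    out = tau_table.copy()
    out["fold_over_rest"] = fold_over_rest
    out["category"] = pd.Categorical(category, categories=list(CATEGORIES))
    out["group"] = group
    return out


def tissue_correlation(profile: pd.DataFrame, gene_subset=None) -> pd.DataFrame:
    """Pearson correlation between tissues on log2(TPM+1) of a gene subset.

    A tissue whose (log) profile is constant over the subset has undefined
    correlations, reported as NaN.
    """
    sub = profile if gene_subset is None else profile.loc[list(gene_subset)]
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 genes for tissue correlation")
    logx = np.log2(sub.values.astype(float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(logx.T)
    return pd.DataFrame(corr, index=sub.columns, columns=sub.columns)


def foldchange_tau_correlation(tau_table: pd.DataFrame):
    """Spearman correlation of log2 fold-change over other tissues vs tau.

    Uses tie-corrected rank correlation over genes with a finite positive
    fold; returns (rho, p).
    """
    fold = tau_table["fold_over_rest"].values.astype(float)
    tau = tau_table["tau"].values.astype(float)
    mask = np.isfinite(fold) & (fold > 0) & np.isfinite(tau)
    if mask.sum() < 10:
        raise ValueError("need at least 10 genes with finite fold-change")
    log2fc = np.log2(fold[mask])
    res = stats.spearmanr(log2fc, tau[mask])
    return float(res.statistic), float(res.pvalue)
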