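"""Association of gene-label sets (e.g. genes under positive selection) with
tissue specificity and expression level.

Label sets such as GUPS (genes under positive selection), transcription
factors, or immune/hypoxia-related genes arrive as plain gene lists; the
analysis compares their tau and log2(TPM+1) distributions against the
tissue-specific genes and the rest of the atlas, cross-tabulates labels
against the four expression categories, and reports per-tissue mean
expression of each set.

The Kruskal-Wallis H statistic (with tie correction) and the one-way ANOVA F
are computed from their definitions here; the scipy versions serve as
independent cross-checks in the test suite only.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["GeneLabelSet", "kruskal_wallis", "anova_oneway", "compare_label_sets"]


@dataclass
class GeneLabelSet:
    name: str
    genes: list

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene ids in label set {self.name!r}")


def kruskal_wallis(groups) -> tuple:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    H = 12 / (n (n+1)) * sum_j R_j^2 / n_j - 3 (n+1), divided by the tie
    correction 1 - sum(t^3 - t) / (n^3 - n) over tied value multiplicities t.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    pooled = np.concatenate(groups)
    n = pooled.size
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical across all groups; H undefined")
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = ranks[start:start + g.size].sum()
        h += rsum**2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    h /= tie
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def anova_oneway(groups) -> tuple:
    """Classical one-way ANOVA F = between mean square / within mean square."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    n = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within <= 0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def compare_label_sets(
    tau_table: pd.DataFrame,
    atlas,
    labels,
) -> dict:
    """Distributional comparison of label sets against the atlas categories.

    Returns a dict with:

    ``summary``      per-set size, tau and expression summaries;
    ``crosstab``     label x category counts (rows sum to the intersected
                     set sizes);
    ``tissue_means`` per-tissue mean log2(TPM+1) of each set;
    ``tests``        pairwise Kruskal-Wallis on tau and expression between
                     each label set and (a) tissue-specific genes, (b) the
                     complement of the set, and (c) the complement excluding
                     tissue-specific genes.

    Label sets with no genes in the atlas are warned about and skipped.
    """
    expr = atlas.expression
    logx = np.log2(expr.values.astype(float) + 1.0)
    mean_log = pd.Series(logx.mean(axis=1), index=expr.index)
    tissue_mean_log = pd.DataFrame(
        {
            t: logx[:, [list(expr.columns).index(s) for s in atlas.samples_of(t)]].mean(axis=1)
            for t in atlas.tissues
        },
        index=expr.index,
    )
    universe = tau_table.index
    ts_genes = universe[tau_table["category"] == "TissueSpecific"]

    kept = []
    for ls in labels:
        inter = [g for g in ls.genes if g in set(universe)]
        if not inter:
            warnings.warn(f"label set {ls.name!r} has no genes in the atlas; skipped")
            continue
        kept.append((ls.name, inter))

    summary_rows, crosstab_rows, tissue_rows, test_rows = [], [], [], []
    for name, genes in kept:
        tau_g = tau_table.loc[genes, "tau"]
        exp_g = mean_log.loc[genes]
        summary_rows.append(
            {
                "label": name,
                "n_genes": len(genes),
                "median_tau": float(tau_g.median()),
                "mean_tau": float(tau_g.mean()),
                "median_log2_tpm": float(exp_g.median()),
                "mean_log2_tpm": float(exp_g.mean()),
            }
        )
        counts = tau_table.loc[genes, "category"].value_counts()
        crosstab_rows.append({"label": name, **counts.to_dict()})
        tissue_rows.append(
            {"label": name, **tissue_mean_log.loc[genes].mean(axis=0).to_dict()}
        )
        complement = universe.difference(genes)
        complement_nots = complement.difference(ts_genes)
        contrasts = [
            ("TissueSpecific", ts_genes.difference(genes)),
            ("complement", complement),
            ("complement_excl_TS", complement_nots),
        ]
        for other_name, other in contrasts:
            if len(other) < 2 or len(genes) < 2:
                continue
            for what, values in (("tau", tau_table["tau"]), ("log2_tpm", mean_log)):
                try:
                    h, p = kruskal_wallis([values.loc[genes], values.loc[other]])
                except ValueError:
                    h, p = np.nan, np.nan
                test_rows.append(
                    {"label": name, "versus": other_name, "variable": what,
                     "H": h, "p": p}
                )

    crosstab = pd.DataFrame(crosstab_rows).set_index("label") if crosstab_rows else pd.DataFrame()
    if not crosstab.empty:
        from .config import CATEGORIES

        crosstab = crosstab.reindex(columns=list(CATEGORIES), fill_value=0).fillna(0).astype(int)
    return {
        "summary": pd.DataFrame(summary_rows),
        "crosstab": crosstab,
        "tissue_means": pd.DataFrame(tissue_rows).set_index("label") if tissue_rows else pd.DataFrame(),
        "tests": pd.DataFrame(test_rows),
    }
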