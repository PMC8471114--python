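"""Seeded synthetic multitissue atlas with planted ground truth.

The generator emulates a deep bulk RNA-seq atlas of 10 tissues with two
pooled libraries per tissue. Every gene is planted in exactly one of the four
expression categories; tissue-specific and group-enriched genes receive
log-uniform folds of at least ``specific_fold`` over baseline, housekeeping
("ExpressedInAll") genes are flat, and mixed genes combine moderate (2-4x)
enrichment in a few tissues with 1-2 tissues pushed below the 1-TPM detection
level. Mixed genes therefore show the stretched tau distribution expected of
that class while remaining un-claimable by the other three categories.

Co-expression modules are planted among the tissue-specific genes of a tissue
by adding a latent per-sample factor (in log2 space) to the members. The
factor is centered within each tissue's replicates, so it creates sample-level
co-expression without moving tissue means: planted categories stay exactly
recoverable on a noiseless fixture.

TPM is the counts-per-million surrogate with all gene lengths fixed at 1; the
downstream stages only ever use TPM relatively, so lengths add nothing.
Counts are negative-binomial with variance mu + phi*mu^2.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ExpressionAtlas
from .config import CATEGORIES, SimConfig

__all__ = ["SyntheticTruth", "simulate_atlas", "simulate_ppi", "write_fixture"]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated atlas.

    ``genes``: per-gene category, target tissue(s) and planted fold.
    ``modules``: planted co-expression modules with their active tissue.
    ``cliques``: planted PPI cliques; each clique's genes are a subset of one
    planted module.
    """

    genes: pd.DataFrame
    modules: list = field(default_factory=list)
    cliques: list = field(default_factory=list)

    def category_counts(self) -> pd.Series:
        return self.genes["category"].value_counts().reindex(CATEGORIES, fill_value=0)


def _plant_means(config: SimConfig, rng: np.random.Generator):
    """Build the genes x tissues log2 mean matrix and the per-gene truth."""
    G, T = config.n_genes, config.n_tissues
    tissues = config.tissue_names()
    cats = rng.choice(
        list(CATEGORIES), size=G,
        p=[config.category_fractions[c] for c in CATEGORIES],
    )
    base = config.baseline_log2_mean + config.baseline_log2_sd * rng.standard_normal(G)
    base = np.maximum(base, 0.0)  # keep every planted gene comfortably detected
    M = np.repeat(base[:, None], T, axis=1)

    target = np.full(G, "", dtype=object)
    fold = np.ones(G)
    # "off" tissues of mixed genes sit at ~mixed_off_tpm after the per-sample
    # rescaling to 1e6; the expected column total sets the conversion
    off_log2 = np.log2(config.mixed_off_tpm * np.sum(2.0**base) / 1e6)
    lo_f, hi_f = np.log2(config.specific_fold), np.log2(config.specific_fold * config.fold_spread)
    for g in range(G):
        cat = cats[g]
        if cat == "TissueSpecific":
            t = int(rng.integers(T))
            f = 2.0 ** rng.uniform(lo_f, hi_f)
            M[g, t] += np.log2(f)
            target[g] = tissues[t]
            fold[g] = f
        elif cat == "GroupEnriched":
            k = int(rng.integers(config.group_size_range[0], config.group_size_range[1] + 1))
            idx = rng.choice(T, size=k, replace=False)
            f = 2.0 ** rng.uniform(lo_f, hi_f)
            M[g, idx] += np.log2(f)
            target[g] = ";".join(sorted(tissues[i] for i in idx))
            fold[g] = f
        elif cat == "Mixed":
            ne = int(rng.integers(config.mixed_subset_range[0], config.mixed_subset_range[1] + 1))
            noff = int(rng.integers(config.mixed_off_range[0], config.mixed_off_range[1] + 1))
            idx = rng.choice(T, size=ne + noff, replace=False)
            f = rng.uniform(*config.mixed_enrich_range)
            M[g, idx[:ne]] += np.log2(f)
            M[g, idx[ne:]] = off_log2
            target[g] = ";".join(sorted(tissues[i] for i in idx[:ne]))
            fold[g] = f
        # ExpressedInAll: flat baseline, fold 1
    truth = pd.DataFrame(
        {"category": cats, "target": target, "fold": fold},
        index=pd.Index([f"g{i:05d}" for i in range(G)], name="gene_id"),
    )
    return M, truth


def _plant_modules(config: SimConfig, truth: pd.DataFrame, rng: np.random.Generator):
    """Choose module member genes among each tissue's tissue-specific genes."""
    gene_ids = truth.index.to_numpy()
    ts = truth["category"] == "TissueSpecific"
    pools = {
        t: gene_ids[(ts & (truth["target"] == t)).to_numpy()]
        for t in config.tissue_names()
    }
    ranked = sorted(pools, key=lambda t: (-len(pools[t]), t))
    lo, hi = config.module_size_range
    modules = []
    for m, tissue in enumerate(ranked[: config.n_modules]):
        pool = pools[tissue]
        if len(pool) < max(3, lo // 2):
            continue
        size = min(int(rng.integers(lo, hi + 1)), len(pool))
        members = sorted(rng.choice(pool, size=size, replace=False))
        modules.append({"id": f"M{m + 1}", "tissue": tissue, "genes": members})
    return modules


def simulate_atlas(config: SimConfig):
    """Generate (ExpressionAtlas, counts DataFrame, SyntheticTruth).

    The same config (including seed) always produces bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T, R, G = config.n_tissues, config.n_replicates, config.n_genes
    tissues = config.tissue_names()

    M, truth = _plant_means(config, rng)
    modules = _plant_modules(config, truth, rng)

    sample_ids = [f"{t}_r{j + 1}" for t in tissues for j in range(R)]
    tissue_idx = np.repeat(np.arange(T), R)
    S = T * R

    L = M[:, tissue_idx] + config.noise_log2_sd * rng.standard_normal((G, S))

    gene_pos = {g: i for i, g in enumerate(truth.index)}
    for mod in modules:
        rows = np.array([gene_pos[g] for g in mod["genes"]])
        loading = rng.uniform(0.75, 1.25, size=len(rows))
        f = config.module_factor_sd * rng.standard_normal(S)
        # center within each tissue so tissue means (and planted categories)
        # are untouched while replicates co-vary
        for t in range(T):
            cols = tissue_idx == t
            f[cols] -= f[cols].mean()
        L[rows] += loading[:, None] * f[None, :]

    rel = 2.0 ** L
    colsum = rel.sum(axis=0)
    tpm = rel / colsum * 1e6
    mu = rel / colsum * float(config.library_size_mean)
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    expression = pd.DataFrame(tpm, index=truth.index.copy(), columns=sample_ids)
    counts_df = pd.DataFrame(counts, index=truth.index.copy(), columns=sample_ids)
    design = pd.DataFrame(
        {"sample_id": sample_ids, "tissue": [tissues[i] for i in tissue_idx]}
    )
    atlas = ExpressionAtlas(expression=expression, design=design)
    return atlas, counts_df, SyntheticTruth(genes=truth, modules=modules)


def simulate_ppi(truth: SyntheticTruth, config: SimConfig) -> pd.DataFrame:
    """Scored protein-interaction edge list with planted cliques.

    Background edges are uniform over gene pairs with Uniform(0,1) scores;
    planted cliques (complete subgraphs of >=3 genes inside a planted module)
    carry Uniform(0.75,1) scores, so they survive the strict 0.7 score gate.
    Records the planted cliques on ``truth.cliques``. Returns a DataFrame
    with columns protein1, protein2, combined_score (one row per unordered
    pair, protein1 < protein2).
    """
    if config.ppi_clique_fraction > 0 and not truth.modules:
        raise ValueError("truth contains no modules to plant cliques in")
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = truth.genes.index.to_numpy()
    G = len(gene_ids)

    edges: dict = {}
    while len(edges) < config.ppi_background_edges:
        i, j = rng.integers(0, G, size=2)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        score = rng.uniform()
        if key not in edges:
            edges[key] = score

    truth.cliques = []
    n_cliques = int(round(config.ppi_clique_fraction * len(truth.modules)))
    if n_cliques > 0:
        chosen = rng.choice(len(truth.modules), size=n_cliques, replace=False)
        lo, hi = config.ppi_clique_size_range
        for mi in sorted(chosen):
            mod = truth.modules[mi]
            if len(mod["genes"]) < 3:
                raise ValueError(f"module {mod['id']} too small for a clique")
            size = int(rng.integers(lo, min(hi, len(mod["genes"])) + 1))
            members = sorted(rng.choice(mod["genes"], size=size, replace=False))
            pos = {g: np.flatnonzero(gene_ids == g)[0] for g in members}
            for a in range(size):
                for b in range(a + 1, size):
                    i, j = pos[members[a]], pos[members[b]]
                    key = (min(i, j), max(i, j))
                    edges[key] = max(edges.get(key, 0.0), rng.uniform(0.75, 1.0))
            truth.cliques.append(
                {"module": mod["id"], "tissue": mod["tissue"], "genes": members}
            )

    rows = [
        (gene_ids[i], gene_ids[j], score)
        for (i, j), score in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


def write_fixture(dir_path, atlas: ExpressionAtlas, counts: pd.DataFrame,
                  truth: SyntheticTruth, ppi: pd.DataFrame) -> dict:
    """Write expression.tsv, counts.tsv, design.tsv, ppi.tsv and truth.json.

    All tables are tab-separated UTF-8 with a header row; the expression and
    count matrices have ``gene_id`` as first column. Files round-trip through
    the readers in :mod:`tissueatlas.io` bit-exactly.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "ppi": out / "ppi.tsv",
        "truth": out / "truth.json",
    }
    # 17 significant digits: float64 round-trips bit-exactly through the readers
    atlas.expression.rename_axis("gene_id").to_csv(
        paths["expression"], sep="\t", float_format="%.17g")
    counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    atlas.design.to_csv(paths["design"], sep="\t", index=False)
    ppi.to_csv(paths["ppi"], sep="\t", index=False)
    payload = {
        "genes": {
            g: {"category": row["category"], "target": row["target"], "fold": row["fold"]}
            for g, row in truth.genes.iterrows()
        },
        "modules": truth.modules,
        "cliques": truth.cliques,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
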