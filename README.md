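# tissueatlas

Analysis toolkit for multitissue bulk RNA-seq expression atlases, built for
the kind of study that profiles ~10 vital tissues of a non-model vertebrate
(fish atlases being the motivating case) with a couple of pooled sequencing
libraries per tissue. It answers the standard questions such an atlas poses:
which genes are tissue-specific, which are housekeeping, which co-expression
modules light up in which tissue, and which protein-interaction subnetworks
are private to a tissue.

## What it computes

**Tissue specificity (τ).** For a gene *g* measured over *N* tissues
(arithmetic-mean TPM per tissue, x̄ᵢ):

    τ = Σᵢ (1 − x̄ᵢ / x̄_max) / (N − 1)

τ = 0 for uniform expression, τ = 1 for expression confined to one tissue.

**Four-way classification** (Human-Protein-Atlas style, precedence order):

| category | rule |
|---|---|
| TissueSpecific | τ > 0.85 and top tissue ≥ 5× every other tissue |
| GroupEnriched | τ > 0.5 and a group of 2–7 tissues ≥ 5× the rest |
| ExpressedInAll | ≥ 1 TPM in every tissue |
| Mixed | everything else detected |

Genes with grand-mean expression ≤ 1 TPM (inclusive) and annotated ncRNAs
are removed before τ is computed.

**One-vs-all differential expression.** Per gene and focal tissue, a
negative-binomial GLM with log library-size offset; the likelihood-ratio
statistic of the focal-tissue indicator is referred to χ²(1). A gene is a
DEG when log2FC > 3 and p < 0.05 (both strict; BH q-values are reported but
not used for the call).

**Co-expression modules.** Soft-power adjacency |r|^β on log2(TPM+1),
topological-overlap dissimilarity, average-linkage clustering with a static
cut, and a membership-pruning pass. Module activity per tissue is a
permutation NES (null = random gene sets of equal size); hubs are the genes
with the highest intramodule connectivity.

**Tissue-specific PPI networks.** A STRING-style scored edge list is
filtered at score > 0.7 (strict); the subnetwork of a tissue is the induced
subgraph over genes that are both tissue-specific for it and members of a
module significantly active in it, keeping components of ≥ 3 proteins.

**Label-set association.** Supplied gene lists (genes under positive
selection, transcription factors, ...) are compared against the
tissue-specific genes and the rest of the atlas by tau and expression level
(Kruskal–Wallis, one-way ANOVA, both implemented from their definitions).

A seeded synthetic-data generator plants all of this structure —
category labels with known folds, latent-factor co-expression modules, PPI
cliques inside modules — so every stage is testable against ground truth.

## Worked example

```python
from tissueatlas import SimConfig, simulate_atlas
from tissueatlas.atlas import (average_replicates, filter_genes, compute_tau,
                               classify_genes, foldchange_tau_correlation)

cfg = SimConfig(n_genes=2000, seed=7)           # 10 tissues x 2 replicates
atlas, counts, truth = simulate_atlas(cfg)
profile = filter_genes(average_replicates(atlas))
table = classify_genes(profile, compute_tau(profile))
print(table["category"].value_counts().to_string())
rho, p = foldchange_tau_correlation(table)
print(f"Spearman rho(log2 fold, tau) = {rho:.3f} (p = {p:.2e})")
```

prints

```
category
Mixed             713
ExpressedInAll    590
GroupEnriched     407
TissueSpecific    290
Spearman rho(log2 fold, tau) = 0.656 (p = 3.07e-246)
```

i.e. the four categories partition the 2,000 retained genes in roughly the
proportions the generator planted (35.7 / 29.8 / 19.5 / 15 %), and the log2
fold-change of a gene's top tissue over the rest correlates positively with
τ, as it must when tissue-specific genes are genuinely upregulated in a
single tissue. Per-gene rows carry τ, the maximal tissue, its TPM, the fold
over the next tissue and the assigned category.

The same analysis end to end, from the shell:

```sh
tissueatlas run --seed 7 --outdir run1 --config config.yaml   # or defaults
tissueatlas summarize --outdir run1
```

which writes `tau_classification.tsv`, `de_results.tsv`, `modules.gmt`,
`module_activity.tsv`, `hubs.tsv`, per-tissue network edge lists and the
summary tables, plus a `manifest.json` with parameters and input checksums.
Identical config and seed reproduce every file byte for byte.

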