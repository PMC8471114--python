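# Methods

This note records the models, parameter choices and numerical decisions
behind `tissueatlas`, and what the synthetic benchmark does and does not
demonstrate about real data.

## Expression atlas and τ

The pipeline starts from a genes × samples TPM matrix and a sample → tissue
design. Replicates are combined by the arithmetic mean per tissue; genes
whose grand mean over tissues is ≤ `min_mean` (default 1 TPM, removal
inclusive at the threshold) or that appear in a supplied ncRNA list are
dropped before anything else. τ is computed on the tissue-mean profile with
N = number of tissues:

    τ_g = Σᵢ (1 − x̄_gi / x̄_g,max) / (N − 1)

τ is undefined for an all-zero profile; the filter guarantees that cannot
be reached through the pipeline, and `compute_tau` raises if called on one
directly.

### Classification

Categories are assigned with precedence TissueSpecific → GroupEnriched →
ExpressedInAll → Mixed, so they partition the retained genes by
construction. Two decisions were genuinely open:

* **"5-fold higher than all other tissues"** is read against the *maximum*
  of the other tissue means — the strictest reading, and the one the Human
  Protein Atlas scheme uses. The comparison is inclusive (exactly 5-fold
  qualifies).
* **Group search.** For GroupEnriched the tissues are sorted descending
  (ties broken by tissue name, so results are deterministic) and the
  smallest k ∈ [2, 7] with min(top-k) ≥ 5 × max(rest) defines the group.
* **Detection threshold.** ExpressedInAll requires ≥ `detect_tpm`
  (default 1 TPM) in every tissue; the threshold is exposed because no
  single value is canonical.

DE results are deliberately *not* an input to classification; the two are
parallel analyses of the same matrix.

Tissue similarity (Pearson, on the tissue-specific gene subset) and the
fold-change–versus–τ Spearman correlation are computed on log2(TPM+1); the
log transform for correlation displays is a convention choice, not a
modelling claim.

## Differential expression

Counts are modelled per gene as NB(μ, φ) with variance μ + φμ², log link
and log library-size offset (counts-per-total normalization; TMM is
deliberately not re-implemented — DEG calls feed no downstream stage
numerically, so the simpler offset keeps the model transparent). The
one-vs-all test compares intercept-only against intercept + focal-tissue
indicator by the likelihood ratio on χ²(1); log2FC is the indicator
coefficient divided by ln 2. The DEG rule is log2FC > 3 AND p < 0.05, both
strict, signed (upregulation in the focal tissue); an `absolute` flag calls
strong downregulation too. No multiple-testing correction enters the call;
BH q-values are written alongside for reference.

**Dispersion estimation** is method-of-moments with two corrections that
matter at atlas-like replication (2–3 libraries per tissue):

1. moments are pooled *within tissue groups* (weighted by residual degrees
   of freedom) so genuine between-tissue differences do not masquerade as
   biological noise, and
2. the denominator uses the unbiased estimate of μ², namely m̄² − s²/n,
   because E[m̄²] = μ² + Var(m̄); without this the estimator is biased low
   at n = 3 and the test becomes anticonservative.

Gene estimates are shrunk toward the trimmed-mean (10%) common dispersion
with weight n_common/(n_common + n_samples), n_common = 10, and floored at
1e-6. Under a null simulation (2,000 genes, 3 vs 3, φ = 0.2) the observed
type-I rate at nominal 0.05 is ≈ 0.05–0.07; power for a planted 16-fold
gene at φ = 0.1 is ≈ 0.97.

**Fitting** is Fisher scoring (IRLS) vectorized across genes, 80 iterations
maximum, convergence at max |Δβ| < 1e-10 with a 1e-6 acceptance band;
linear predictors are clipped to ±40 to survive separation (a group with
all-zero counts), and such fits are flagged unconverged with a missing
p-value rather than reported. The log-likelihoods agree with brute-force
Nelder–Mead maximization to ~1e-13 on single-gene instances.

## Co-expression modules

Pearson correlations across samples of log2(TPM+1), soft-power adjacency
|r|^β, unsigned topological overlap, average linkage, static cut at height
0.995, minimum module size 10 (below the conventional 30 so that modules in
the mid-teens — the realistic size for a 20-sample atlas — survive).

* **β selection.** The smallest β ∈ 1..20 whose degree distribution fits a
  *decreasing* log-log line with R² ≥ 0.8 (the signed scale-free criterion;
  an unsigned fit rewards degenerate two-bin fits with positive slope).
  Tissue-blocked correlation structure never fits a power law well, so when
  no candidate qualifies the conventional fixed power by sample count is
  used (unsigned networks: 10 below 20 samples, 9 for 20–29, 8 for 30–39,
  else 7); when the caller cannot supply a sample count the fallback is 6.
* **Membership pruning.** After the cut, a member whose mean adjacency to
  the rest of its cluster is below 0.1× the cluster median is dropped.
  Chance |r| ≈ 0.4 correlations otherwise attach a handful of unrelated
  genes to any strong module at the permissive static cut; the planted
  members sit orders of magnitude above the pruning line, so the threshold
  is not delicate.
* **Detection universe.** In the pipeline, modules are detected among the
  genes classified TissueSpecific (variance-capped at `n_top`), matching
  the definition of differential co-expression modules as subsets of
  tissue-specific genes; a global variance filter would instead hand the
  slots to high-variance group-enriched genes.

**Module activity (NES).** Observed score = mean gene-standardized
log2(TPM+1) of the module genes over a tissue's samples; the null is the
same score for `n_perm` random gene sets of equal size (gene-set
permutation — with two replicates per tissue, sample permutation has no
support); NES = (obs − null mean)/null sd and p is the upper-tail
permutation probability with +1 smoothing. Genes constant up to floating
error are assigned z = 0 rather than 0/0. Caveat: because TPM couples genes
within a sample, a *strictly* flat gene set in a strongly structured atlas
can drift mildly with the per-sample scale factor; the calibration claim
(≤ 5% of module–tissue pairs significant at 0.05) holds under exchangeable
data, which is what the null test checks.

Hubs are the top-k genes by intramodule connectivity (row sums of the
adjacency restricted to the module), ties broken by gene id.

## Tissue-specific PPI networks

Edges with score > 0.7 (strict, per the STRING "high confidence"
convention) survive; scores above 1 anywhere are taken as the 0–1000 scale
and divided by 1000; duplicate unordered pairs keep the maximum score. The
gate for tissue t is conjunctive and per-protein: classified TissueSpecific
with maximal tissue t, AND member of at least one module with NES > 0 and
p < `activity_p` (default 0.05) in t. "Differentially co-expressed" has no
published formula; module membership with significantly positive activity
is the operationalization used here. Only connected components with ≥ 3
proteins are reported (the smallest meaningful subnetwork); tissues whose
gate yields nothing produce a valid empty network — on realistic data most
tissues do. Network hubs rank by degree, then summed incident scores, then
gene id.

## Label-set association

Gene lists (e.g. genes under positive selection) are intersected with the
atlas; the report compares τ and mean log2(TPM+1) distributions against
(a) the tissue-specific genes, (b) the full complement and (c) the
complement excluding tissue-specific genes — both complement definitions
are reported because "non-labelled" is ambiguous. Kruskal–Wallis H (with
tie correction) and one-way ANOVA F are implemented from their definitions
and cross-checked against independent implementations in the tests. The
selection scan that would *produce* such a label set is out of scope by
design; labels arrive as files.

## Synthetic data generator

The generator emulates a 10-tissue atlas with 2 libraries per tissue and
5,000 genes by default, category proportions 15 / 19.5 / 29.8 / 35.7 %
(tissue-specific / group-enriched / expressed-in-all / mixed — the
proportions observed in deep vertebrate multitissue atlases).

* Baseline log2 abundance ~ Normal(4, 1.5), floored at 0 so every planted
  gene stays comfortably detected after TPM rescaling.
* TissueSpecific and GroupEnriched folds are log-uniform on
  [`specific_fold`, 8×`specific_fold`] (default [8, 64]); with equal
  within-group folds, planted τ = (N−k)(1−1/f)/(N−1), so the default range
  keeps planted genes clear of the τ cut-offs with margin against noise.
* Group sizes default to 2–4 tissues: at k = 5 and modest folds the planted
  τ drops below the 0.5 Group-Enriched band, i.e. larger groups would be
  planted as unrecoverable; observed atlases are dominated by 2-tissue
  groups.
* Mixed genes get 2–4 tissues at 2–4-fold *plus* 1–2 tissues pushed to
  ≈ 0.2 TPM. The sub-detection tissues are what keeps them out of
  ExpressedInAll (a moderately enriched gene detected everywhere *is*
  ExpressedInAll under the precedence rules), and with ≥ 8 detected
  tissues they cannot qualify as GroupEnriched either. The off level is
  specified in TPM and converted through the expected column total, so it
  does not drift with gene count.
* Modules are planted among the tissue-specific genes of a tissue by adding
  a latent per-sample factor (sd 0.5 in log2, loadings 0.75–1.25) that is
  *centered within each tissue's replicates*: members co-vary across
  samples, but tissue means — and therefore the planted categories — are
  untouched, which is what makes exact noiseless recovery possible.
* TPM is counts-per-million with all gene lengths 1 (the analysis only uses
  TPM relatively, so lengths would add nothing testable); per-sample TPM
  columns sum to 1e6 exactly. Counts are NB with mean = library share ×
  1e6 and dispersion `nb_dispersion` (0 ⇒ Poisson).
* PPI: uniform background edges with Uniform(0,1) scores; planted cliques
  (3–6 genes inside a module) with Uniform(0.75, 1) scores, so they survive
  the strict 0.7 gate.
* A single `noise_log2_sd` covers both biological and library variation;
  the study design this emulates pools individuals into two libraries per
  tissue, and nothing in the published design separates the two variance
  components, so the generator does not pretend to.

**What passing tests show — and don't.** Recovery results on this generator
demonstrate that the implementations are correct against their own model
(NB counts, log-normal noise, clean planted folds, independent tissues).
Real atlases add gene-length effects, correlated tissues, batch structure,
composition shifts from a few dominating transcripts (visible here only in
miniature through TPM rescaling), and annotation error; calibration numbers
(type-I ≈ 0.05, NES null ≤ 5%) should be read as model-faithfulness checks,
not as guarantees for arbitrary data.

## Problem sizes and determinism

Defaults are chosen so a complete run (simulate → atlas → DE over 10
tissues → modules → networks → labels → summary, 5,000 genes) finishes in a
few seconds on one CPU; the simulation-heavy checks (200 power repeats,
50-seed nulls) each stay in the seconds-to-a-minute range. All randomness
flows from one integer seed through `numpy.random.default_rng`; expression
matrices are written with 17 significant digits and read back with
round-trip float parsing, so a rerun with the same config and seed is
byte-identical, manifest included.
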