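"""Configuration objects for the simulator and the pipeline.

All stochastic stages take their randomness from a single integer seed, so a
config plus a seed fully determines every output file.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

#: Category labels of the four-way expression classification, in precedence order.
CATEGORIES = ("TissueSpecific", "GroupEnriched", "ExpressedInAll", "Mixed")

#: Tissue names used by the simulator for the default 10-tissue design.
DEFAULT_TISSUES = (
    "brain", "gills", "head_kidney", "heart", "liver",
    "muscle", "ovary", "skin", "spleen", "testis",
)


def _default_fractions() -> dict:
    # Proportions of the four categories in a deeply sequenced vertebrate
    # multitissue atlas (tissue-specific / group-enriched / expressed-in-all / mixed).
    return {
        "TissueSpecific": 0.150,
        "GroupEnriched": 0.195,
        "ExpressedInAll": 0.298,
        "Mixed": 0.357,
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic multitissue expression atlas.

    The defaults emulate a 10-tissue design with two sequencing libraries per
    tissue and ~5,000 protein-coding genes, with planted tissue-specific
    (>=5-fold, tau>0.85), group-enriched (2-4 tissues), housekeeping
    (tau<0.3) and mixed genes, plus co-expression modules driven by latent
    per-sample factors and protein-interaction cliques among module genes.
    """

    n_tissues: int = 10
    n_replicates: int = 2
    n_genes: int = 5000
    category_fractions: dict = field(default_factory=_default_fractions)
    #: minimum planted fold of tissue-specific / group-enriched genes (>=5)
    specific_fold: float = 8.0
    #: folds are drawn log-uniform on [specific_fold, specific_fold*fold_spread]
    fold_spread: float = 8.0
    group_size_range: tuple = (2, 4)
    #: mixed genes: moderate enrichment in a small tissue subset ...
    mixed_enrich_range: tuple = (2.0, 4.0)
    mixed_subset_range: tuple = (2, 4)
    #: ... plus 1-2 tissues pushed below the detection level
    mixed_off_range: tuple = (1, 2)
    #: approximate TPM assigned to the "off" tissues of mixed genes
    mixed_off_tpm: float = 0.2
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    #: per-sample log2 expression noise (0 gives a noiseless fixture)
    noise_log2_sd: float = 0.2
    #: NB overdispersion phi, variance = mu + phi*mu^2 (0 gives Poisson counts)
    nb_dispersion: float = 0.1
    library_size_mean: int = 1_000_000
    n_modules: int = 7
    module_size_range: tuple = (14, 55)
    #: sd of the latent per-sample module factor (log2 space, tissue-centered)
    module_factor_sd: float = 0.5
    ppi_background_edges: int = 2000
    #: fraction of planted modules that receive a PPI clique
    ppi_clique_fraction: float = 0.6
    ppi_clique_size_range: tuple = (3, 6)
    seed: int = 0

    def validate(self) -> None:
        fr = self.category_fractions
        if set(fr) != set(CATEGORIES):
            raise ValueError(f"category_fractions must have keys {CATEGORIES}")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_fractions sum to {total}, expected 1")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")
        lo, hi = self.group_size_range
        if not (2 <= lo <= hi <= min(7, self.n_tissues - 3)):
            raise ValueError(
                f"group_size_range {self.group_size_range} must lie within "
                f"[2, {min(7, self.n_tissues - 3)}] for n_tissues={self.n_tissues}"
            )
        if self.baseline_log2_sd <= 0:
            raise ValueError("baseline_log2_sd must be > 0")
        if self.noise_log2_sd < 0:
            raise ValueError("noise_log2_sd must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.specific_fold < 5:
            raise ValueError("specific_fold must be >= 5")
        if self.n_replicates < 1 or self.n_genes < 10:
            raise ValueError("need n_replicates >= 1 and n_genes >= 10")

    def tissue_names(self) -> list:
        if self.n_tissues == len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES)
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Stage thresholds default to the values the analysis is built around:
     1 TPM grand-mean filter (inclusive removal), tau>0.85 with >=5-fold for
    tissue-specific calls, tau>0.5 and 2-7 tissues for group enrichment,
    log2FC>3 with p<0.05 for DEG calls, and a strict 0.7 interaction-score
    cut for the PPI network.
    """

    # inputs (ignored when simulate=True: the fixture is generated instead)
    expression: Optional[str] = None
    counts: Optional[str] = None
    design: Optional[str] = None
    ppi: Optional[str] = None
    labels: dict = field(default_factory=dict)       # name -> path
    ncrna: Optional[str] = None                      # optional ncRNA id file
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)

    # atlas stage
    min_mean: float = 1.0
    detect_tpm: float = 1.0
    tau_specific: float = 0.85
    fold_specific: float = 5.0
    tau_group: float = 0.5
    group_max: int = 7

    # differential expression stage
    log2fc_cutoff: float = 3.0
    p_cutoff: float = 0.05
    absolute_log2fc: bool = False

    # co-expression stage
    n_top: int = 2000
    min_module_size: int = 10
    cut_height: float = 0.995
    n_perm: int = 1000

    # PPI network stage
    min_score: float = 0.7
    min_component: int = 3
    activity_p: float = 0.05

    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.tau_specific <= 1 or not 0 <= self.tau_group <= 1:
            raise ValueError("tau thresholds must lie in [0, 1]")
        if self.min_mean < 0 or self.detect_tpm < 0:
            raise ValueError("expression thresholds must be >= 0")
        if not 0 < self.p_cutoff < 1 or not 0 < self.activity_p < 1:
            raise ValueError("p-value cutoffs must lie in (0, 1)")
        if not 0 <= self.min_score <= 1:
            raise ValueError("min_score must lie in [0, 1]")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")
        self.sim.validate()

    def to_dict(self) -> dict:
        return asdict(self)
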