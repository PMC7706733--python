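"""Configuration objects for the simulator and the pipeline.

``SimConfig`` encodes the study design the synthetic data emulate: two
parental species (5 + 5 males) and their F1 hybrids (3 males) sampled in
five tissues, negative-binomial counts with gene-wise dispersion, and
phased allelic counts under cis / trans / compensatory / null regulatory
regimes.  ``PipelineConfig`` holds the analysis thresholds; its defaults
are the settings used throughout (FDR 0.05, fold-change threshold 1.125,
99 permutations, SNP coverage >= 10, allelic depth > 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import yaml

INHERITANCE_MODES = (
    "conserved",
    "additive",
    "pied_dominant",
    "collared_dominant",
    "overdominant",
    "underdominant",
)
REGIMES = ("cis", "trans", "compensatory", "null")

FIVE_TISSUES = ("brain", "heart", "kidney", "liver", "testis")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_fraction_map(name: str, fractions: Mapping[str, float],
                        allowed: Sequence[str]) -> None:
    total = 0.0
    for key, value in fractions.items():
        if key not in allowed:
            raise ConfigurationError(f"{name}: unknown key {key!r}")
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(f"{name}[{key!r}] = {value} not in [0, 1]")
        total += value
    if total > 1.0 + 1e-9:
        raise ConfigurationError(f"{name} sums to {total} > 1")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the sampling design (5 collared + 5 pied + 3 hybrid
    males, five tissues).  Distributional defaults (dispersion, effect
    size, SNP coverage) are stated modelling assumptions, not estimates
    from any data set; see the methods note.
    """

    n_genes: int = 2000
    n_tissues: int = 5
    n_parent_a: int = 5          # collared flycatcher individuals
    n_parent_b: int = 5          # pied flycatcher individuals
    n_hybrid: int = 3            # F1 hybrid individuals
    # fraction of genes per non-conserved inheritance mode; remainder conserved
    mode_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "additive": 0.05,
        "pied_dominant": 0.05,
        "collared_dominant": 0.05,
        "overdominant": 0.05,
        "underdominant": 0.05,
    })
    effect_size_log2: float = 1.0        # mean |log2 fold change| of divergent genes
    tissue_effect_log2_sd: float = 1.0   # per-gene x tissue baseline spread
    dispersion_log_mean: float = -4.6    # ln scale; median alpha ~ 0.01
    dispersion_log_sd: float = 0.5
    base_log2_range: tuple[float, float] = (5.0, 10.0)  # baseline mean counts 32-1024
    library_size_factors: Optional[Sequence[float]] = None  # default drawn lognormal
    library_size_log_sd: float = 0.15
    # conditional weights for the regulatory regime of a gene given its mode
    regime_fractions: Mapping[str, float] = field(default_factory=lambda: {
        "cis": 0.5,
        "trans": 0.5,
        "compensatory": 0.5,
        "null": 0.5,
    })
    ase_overdispersion: float = 0.02     # beta-binomial rho
    snps_per_gene_mean: float = 6.0
    snp_coverage_mean: float = 30.0
    snp_coverage_shape: float = 10.0     # gamma shape of the coverage mixing
    parental_ase_prob: float = 0.05      # segregating within-species ASE
    filter_violation_prob: float = 0.05  # SNPs built to fail coverage/depth filters
    cne_flag_prob_given_cis: float = 0.3
    cne_flag_prob_given_not_cis: float = 0.1
    z_fraction: float = 0.05             # fraction of genes on the Z chromosome
    tau_de_shift: float = 0.0            # optional planted covariate->DE correlation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tissues", "n_parent_a", "n_parent_b",
                     "n_hybrid", "seed"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ConfigurationError(f"{name} must be an integer, got {value!r}")
        for name in ("n_genes", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        # the population-level ASE rule needs at least two tested individuals
        if self.n_parent_a < 2 or self.n_parent_b < 2 or self.n_hybrid < 2:
            raise ConfigurationError("group sizes must be >= 2")
        _check_fraction_map("mode_fractions", self.mode_fractions,
                            INHERITANCE_MODES[1:])
        for key, value in self.regime_fractions.items():
            if key not in REGIMES:
                raise ConfigurationError(f"regime_fractions: unknown key {key!r}")
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(
                    f"regime_fractions[{key!r}] = {value} not in [0, 1]")
        if not 0.0 <= self.ase_overdispersion < 1.0:
            raise ConfigurationError("ase_overdispersion must be in [0, 1)")
        if self.effect_size_log2 <= 0:
            raise ConfigurationError("effect_size_log2 must be positive")
        if self.snps_per_gene_mean < 2:
            raise ConfigurationError("snps_per_gene_mean must be >= 2")
        if self.snp_coverage_mean <= 0:
            raise ConfigurationError("snp_coverage_mean must be positive")
        for name in ("parental_ase_prob", "filter_violation_prob",
                     "cne_flag_prob_given_cis", "cne_flag_prob_given_not_cis",
                     "z_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} = {value} not a probability")
        if self.library_size_factors is not None:
            sizes = list(self.library_size_factors)
            if any(s <= 0 for s in sizes):
                raise ConfigurationError("library_size_factors must be positive")

    @property
    def tissues(self) -> tuple[str, ...]:
        if self.n_tissues == len(FIVE_TISSUES):
            return FIVE_TISSUES
        return tuple(f"tissue{i + 1}" for i in range(self.n_tissues))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mode_fractions"] = dict(self.mode_fractions)
        d["regime_fractions"] = dict(self.regime_fractions)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "base_log2_range" in data:
            data["base_log2_range"] = tuple(data["base_log2_range"])
        return cls(**data)


@dataclass
class PipelineConfig:
    """Analysis thresholds and switches; defaults follow the study settings."""

    alpha: float = 0.05                  # FDR threshold for DE / ASE calls
    fold_threshold: float = 1.125        # inheritance-mode classification
    n_perm: int = 99                     # bgPCA Monte-Carlo permutations
    min_coverage: int = 10               # per-SNP total coverage filter
    min_allelic_depth: int = 2           # min(A, B) must exceed this
    min_snps: int = 2                    # phased SNPs per gene/individual
    tpm_threshold: float = 1.0           # expressed-gene census cut-off
    dispersion_prior_var: float = 0.25   # log-dispersion shrinkage prior
    lfc_prior_var: Optional[float] = None  # None -> estimated from data
    require_sign_consistency: bool = True  # misexpression needs sign-consistent LFCs
    independent_filtering: bool = False
    tau_log_transform: bool = True
    ase_fallback_rho: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.fold_threshold <= 1:
            raise ConfigurationError("fold_threshold must exceed 1")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
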