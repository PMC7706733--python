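"""Seeded generators for counts, phased allelic counts and annotation.

The generators emulate a two-species + F1-hybrid multi-tissue RNA-seq
design.  Gene expression is negative-binomial with gene-wise dispersion;
each gene x tissue carries a true inheritance mode (how the hybrid mean
relates to the parental means) and a regulatory regime (whether the
divergence is cis-acting, trans-acting, compensatory, or absent), with
the regime dictating the hybrid allelic ratio:

* ``cis``          -- parental divergence with allelic imbalance in hybrids
                      (ratio 2**lfc : 1 on the collared haplotype);
* ``trans``        -- parental divergence, balanced hybrid alleles (0.5);
* ``compensatory`` -- parents conserved, hybrid misexpressed, hybrid
                      allelic imbalance (the cis half of the cancelled pair);
* ``null``         -- no divergence, balanced alleles.

A single global seed is stream-split (one child stream per generator) so
adding one generator call never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig, INHERITANCE_MODES

_DIVERGENT_MODES = ("additive", "pied_dominant", "collared_dominant")
_MISEXPRESSED_MODES = ("overdominant", "underdominant")


@dataclass
class SimTruth:
    """Ground truth of a simulated data set.

    ``gene_tissue`` has one row per gene x tissue (mode, regime, true
    log2 fold change collared/pied, hybrid collared-haplotype fraction);
    ``genes`` has per-gene quantities (NB dispersion, baseline mean,
    cis indicator over tissues).
    """

    gene_tissue: pd.DataFrame
    genes: pd.DataFrame
    config: SimConfig


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(3)
    return {
        "counts": np.random.default_rng(children[0]),
        "alleles": np.random.default_rng(children[1]),
        "annotation": np.random.default_rng(children[2]),
    }


def _draw_modes(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    modes = list(config.mode_fractions)
    probs = np.array([config.mode_fractions[m] for m in modes], float)
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    probs /= probs.sum()
    choices = np.array(modes + ["conserved"], object)
    return rng.choice(choices, size=config.n_genes, p=probs)


def _draw_regimes(rng: np.random.Generator, modes: np.ndarray,
                  config: SimConfig) -> np.ndarray:
    """Regime conditional on mode so the truth invariants hold by design."""
    f = config.regime_fractions
    regimes = np.full(modes.shape, "null", object)
    div = np.isin(modes, _DIVERGENT_MODES)
    mis = np.isin(modes, _MISEXPRESSED_MODES)
    w_ct = np.array([f.get("cis", 0.0), f.get("trans", 0.0)], float)
    if w_ct.sum() == 0:
        w_ct = np.array([0.0, 1.0])
    w_ct = w_ct / w_ct.sum()
    regimes[div] = rng.choice(np.array(["cis", "trans"], object),
                              size=int(div.sum()), p=w_ct)
    w_cn = np.array([f.get("compensatory", 0.0), f.get("null", 0.0)], float)
    if w_cn.sum() == 0:
        w_cn = np.array([0.0, 1.0])
    w_cn = w_cn / w_cn.sum()
    regimes[mis] = rng.choice(np.array(["compensatory", "null"], object),
                              size=int(mis.sum()), p=w_cn)
    return regimes


def _hybrid_ratio(modes: np.ndarray, regimes: np.ndarray, lfc: np.ndarray,
                  effect: float, rng: np.random.Generator) -> np.ndarray:
    """Collared-haplotype read fraction in hybrids per gene."""
    ratio = np.full(modes.shape, 0.5)
    is_cis = regimes == "cis"
    fold = np.exp2(lfc[is_cis])
    ratio[is_cis] = fold / (1.0 + fold)
    comp = regimes == "compensatory"
    # compensatory: hidden cis shift of the configured effect size, sign
    # matching the direction of hybrid misexpression
    sign = np.where(modes[comp] == "overdominant", 1.0, -1.0)
    fold = np.exp2(sign * effect)
    ratio[comp] = fold / (1.0 + fold)
    return ratio


def simulate_counts(config: SimConfig):
    """Simulate the count matrix, sample table and ground truth.

    Returns ``(counts, samples, truth)`` where ``counts`` is a gene x
    sample integer DataFrame, ``samples`` carries (sample, species,
    tissue, individual) and ``truth`` is a :class:`SimTruth`.
    Identical config + seed is bit-for-bit reproducible.
    """
    rng = _streams(config)["counts"]
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)])
    tissues = config.tissues

    individuals = (
        [("collared", f"COL{i + 1:02d}") for i in range(config.n_parent_a)]
        + [("pied", f"PIE{i + 1:02d}") for i in range(config.n_parent_b)]
        + [("hybrid", f"HYB{i + 1:02d}") for i in range(config.n_hybrid)]
    )
    samples = pd.DataFrame(
        [(f"{ind}_{tis}", sp, tis, ind)
         for sp, ind in individuals for tis in tissues],
        columns=["sample", "species", "tissue", "individual"],
    )
    n_samples = len(samples)
    if config.library_size_factors is not None:
        sf = np.asarray(list(config.library_size_factors), float)
        if sf.size != n_samples:
            raise ValueError(
                f"library_size_factors has {sf.size} entries, need {n_samples}")
    else:
        sf = rng.lognormal(mean=0.0, sigma=config.library_size_log_sd,
                           size=n_samples)

    alpha = rng.lognormal(config.dispersion_log_mean, config.dispersion_log_sd,
                          size=config.n_genes)
    lo, hi = config.base_log2_range
    base = np.exp2(rng.uniform(lo, hi, size=config.n_genes))

    truth_rows = []
    count_blocks = np.empty((config.n_genes, n_samples), dtype=np.int64)
    species = samples["species"].to_numpy()
    tissue_col = samples["tissue"].to_numpy()
    effect = config.effect_size_log2

    for tissue in tissues:
        modes = _draw_modes(rng, config)
        regimes = _draw_regimes(rng, modes, config)
        sign = rng.choice([-1.0, 1.0], size=config.n_genes)
        lfc = np.where(np.isin(modes, _DIVERGENT_MODES), sign * effect, 0.0)
        ratio = _hybrid_ratio(modes, regimes, lfc, effect, rng)

        # tissue-specific baseline: expression varies more across tissues
        # than between species, as in real multi-tissue designs
        if config.n_tissues > 1 and config.tissue_effect_log2_sd > 0:
            base_t = base * np.exp2(
                rng.normal(0.0, config.tissue_effect_log2_sd, config.n_genes))
        else:
            base_t = base
        mu_c = base_t * np.exp2(lfc / 2.0)
        mu_p = base_t * np.exp2(-lfc / 2.0)
        mu_h = base_t.copy()  # conserved and additive: log-scale midpoint
        mu_h[modes == "collared_dominant"] = mu_c[modes == "collared_dominant"]
        mu_h[modes == "pied_dominant"] = mu_p[modes == "pied_dominant"]
        mu_h[modes == "overdominant"] = base_t[modes == "overdominant"] * 2.0 ** effect
        mu_h[modes == "underdominant"] = base_t[modes == "underdominant"] * 2.0 ** -effect

        cols = np.flatnonzero(tissue_col == tissue)
        mu_group = {"collared": mu_c, "pied": mu_p, "hybrid": mu_h}
        for j in cols:
            mu = mu_group[species[j]] * sf[j]
            count_blocks[:, j] = _nb_draw(rng, mu, alpha)

        truth_rows.append(pd.DataFrame({
            "gene": genes, "tissue": tissue, "mode": modes,
            "regime": regimes, "true_lfc": lfc, "hybrid_ratio": ratio,
        }))

    counts = pd.DataFrame(count_blocks, index=pd.Index(genes, name="gene"),
                          columns=samples["sample"].to_numpy())
    gene_tissue = pd.concat(truth_rows, ignore_index=True)
    gene_frame = pd.DataFrame({
        "gene": genes, "dispersion": alpha, "base_mean": base,
        "is_cis": gene_tissue.groupby("gene", sort=False)["regime"]
                             .agg(lambda r: bool((r == "cis").any()))
                             .reindex(genes).to_numpy(),
    })
    truth = SimTruth(gene_tissue=gene_tissue, genes=gene_frame, config=config)
    return counts, samples, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) via gamma-Poisson; alpha = 0 is Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha <= 0
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    mixed = ~poisson
    if mixed.any():
        shape = 1.0 / alpha[mixed]
        lam = rng.gamma(shape, alpha[mixed] * mu[mixed])
        out[mixed] = rng.poisson(lam)
    return out


def simulate_allele_counts(truth: SimTruth, config: SimConfig | None = None,
                           genes=None) -> pd.DataFrame:
    """Phased per-SNP allelic counts for every individual, gene and tissue.

    Hybrid SNPs draw the collared-haplotype count from a beta-binomial
    with the gene's true allelic ratio; parental SNPs are balanced unless
    the (gene, individual) carries segregating within-species ASE.  A
    configured fraction of SNPs deliberately violates the coverage /
    allelic-depth filters downstream.
    """
    config = config or truth.config
    rng = _streams(config)["alleles"]
    gene_universe = truth.genes["gene"].to_numpy()
    if genes is not None:
        missing = set(genes) - set(gene_universe)
        if missing:
            raise KeyError(
                f"genes absent from truth: {sorted(missing)[:5]}")
        gene_universe = np.asarray(list(genes))

    ratio_map = truth.gene_tissue.set_index(["gene", "tissue"])["hybrid_ratio"]
    individuals = (
        [("collared", f"COL{i + 1:02d}") for i in range(config.n_parent_a)]
        + [("pied", f"PIE{i + 1:02d}") for i in range(config.n_parent_b)]
        + [("hybrid", f"HYB{i + 1:02d}") for i in range(config.n_hybrid)]
    )
    rho = config.ase_overdispersion
    n_genes = len(gene_universe)

    rows = []
    for species, ind in individuals:
        # segregating within-species ASE: per-gene, per-individual ratio
        seg = rng.random(n_genes) < config.parental_ase_prob
        seg_side = rng.random(n_genes) < 0.5
        seg_ratio = np.where(seg_side, rng.beta(2, 6, n_genes),
                             rng.beta(6, 2, n_genes))
        for tissue in config.tissues:
            if species == "hybrid":
                ratios = ratio_map.loc[
                    [(g, tissue) for g in gene_universe]].to_numpy()
            else:
                ratios = np.where(seg, seg_ratio, 0.5)
            k = 2 + rng.poisson(config.snps_per_gene_mean - 2.0, size=n_genes)
            total = int(k.sum())
            gene_idx = np.repeat(np.arange(n_genes), k)
            ratio_snp = ratios[gene_idx]
            shape = config.snp_coverage_shape
            lam = rng.gamma(shape, config.snp_coverage_mean / shape, size=total)
            coverage = rng.poisson(lam)
            violate = rng.random(total) < config.filter_violation_prob
            coverage[violate] = rng.integers(2, 10, size=int(violate.sum()))
            coverage = np.maximum(coverage, 1)
            if rho > 0:
                a_par = ratio_snp * (1.0 / rho - 1.0)
                b_par = (1.0 - ratio_snp) * (1.0 / rho - 1.0)
                p_snp = rng.beta(a_par, b_par)
            else:
                p_snp = ratio_snp
            hap_a = rng.binomial(coverage, p_snp)
            snp_ord = np.concatenate([np.arange(c) for c in k]) if total else \
                np.array([], int)
            rows.append(pd.DataFrame({
                "gene": gene_universe[gene_idx],
                "individual": ind,
                "species": species,
                "tissue": tissue,
                "snp": [f"s{o + 1}" for o in snp_ord],
                "hap_a": hap_a,
                "hap_b": coverage - hap_a,
                "phase_set": "ps1",
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_annotation(truth: SimTruth, config: SimConfig | None = None,
                        ) -> pd.DataFrame:
    """Per-gene annotation: chromosome class, effective length, CNE flag
    and covariates (PPI, tau, phi, piN/piS, dN/dS, FST).

    The CNE fixed-difference flag is enriched among cis-regime genes
    (``cne_flag_prob_given_cis`` vs ``cne_flag_prob_given_not_cis``).
    Covariate distributions are generic priors; ``tau_de_shift`` plants
    an optional correlation between tau and expression divergence.
    """
    config = config or truth.config
    rng = _streams(config)["annotation"]
    genes = truth.genes["gene"].to_numpy()
    n = len(genes)
    is_cis = truth.genes["is_cis"].to_numpy().astype(bool)
    divergent = (truth.gene_tissue.groupby("gene", sort=False)["true_lfc"]
                 .agg(lambda v: bool((v != 0).any())).reindex(genes)
                 .to_numpy().astype(bool))

    chrom_class = np.where(rng.random(n) < config.z_fraction, "Z", "autosome")
    p_flag = np.where(is_cis, config.cne_flag_prob_given_cis,
                      config.cne_flag_prob_given_not_cis)
    cne_flag = rng.random(n) < p_flag
    tau = np.clip(rng.uniform(0, 1, n)
                  + config.tau_de_shift * divergent, 0.0, 1.0)
    annotation = pd.DataFrame({
        "gene": genes,
        "chrom_class": chrom_class,
        "effective_length": rng.integers(300, 5000, size=n),
        "cne_flag": cne_flag,
        "ppi": rng.poisson(8.0, size=n),
        "tau": tau,
        "phi": truth.genes["dispersion"].to_numpy(),
        "pin_pis": rng.lognormal(np.log(0.2), 0.4, size=n),
        "dn_ds": rng.lognormal(np.log(0.15), 0.5, size=n),
        "fst": rng.beta(2.0, 8.0, size=n),
    })
    return annotation
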