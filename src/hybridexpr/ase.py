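"""Gene-level allele-specific expression from phased SNP counts.

Per (gene, individual, tissue), haplotype counts across phased SNPs are
aggregated in a beta-binomial likelihood-ratio test: under the null each
SNP's haplotype-A count is beta-binomial(coverage, 0.5, rho); under the
alternative the SNPs share a gene-level allelic ratio estimated by
maximum likelihood.  rho is a per-individual genome-wide overdispersion
capturing extra-binomial noise (technical plus residual biological).
p-values are BH-adjusted within individual x tissue, and a gene is
population-ASE when at least two individuals reach adjusted p < alpha
(untested below two tested individuals).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln, xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene", "individual", "tissue", "snp", "hap_a", "hap_b")


def filter_snps(table: pd.DataFrame, min_coverage: int = 10,
                min_allelic_depth: int = 2, min_snps: int = 2) -> pd.DataFrame:
    """Apply the per-SNP and per-gene inclusion filters.

    Keeps SNPs with total coverage >= ``min_coverage`` and minor-
    haplotype depth strictly greater than ``min_allelic_depth``, then
    drops (gene, individual, tissue) units with fewer than ``min_snps``
    surviving SNPs.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"allele count table lacks column {col!r}")
    cov = table["hap_a"] + table["hap_b"]
    depth = table[["hap_a", "hap_b"]].min(axis=1)
    keep = (cov >= min_coverage) & (depth > min_allelic_depth)
    dropped = int((~keep).sum())
    filtered = table[keep]
    unit = ["gene", "individual", "tissue"]
    sizes = filtered.groupby(unit)["snp"].transform("size")
    out = filtered[sizes >= min_snps]
    logger.info("filter_snps: dropped %d SNPs, %d rows in thin units",
                dropped, int(len(filtered) - len(out)))
    return out.reset_index(drop=True)


def estimate_overdispersion(table: pd.DataFrame, fallback: float = 0.05,
                            min_snps: int = 50) -> float:
    """Method-of-moments beta-binomial overdispersion around ratio 0.5.

    Uses all SNPs of one individual.  With coverage n, E[(a - n/2)^2] =
    (n/4)(1 + (n - 1) rho); solving over all SNPs with n >= 2 gives rho,
    clamped to [0, 0.5].  Falls back to ``fallback`` when fewer than
    ``min_snps`` informative SNPs are available.
    """
    a = table["hap_a"].to_numpy(float)
    n = a + table["hap_b"].to_numpy(float)
    informative = n >= 2
    a, n = a[informative], n[informative]
    if a.size < min_snps:
        logger.warning("overdispersion fallback: only %d informative SNPs",
                       a.size)
        return fallback
    num = np.sum((a - n / 2.0) ** 2 - n / 4.0)
    den = np.sum(n * (n - 1.0) / 4.0)
    if den <= 0:
        logger.warning("overdispersion undefined; using fallback %.3f", fallback)
        return fallback
    return float(np.clip(num / den, 0.0, 0.5))


def _binom_loglik(a: np.ndarray, n: np.ndarray, r: float) -> float:
    return float(np.sum(xlogy(a, r) + xlogy(n - a, 1.0 - r)))


def _bb_loglik(a: np.ndarray, n: np.ndarray, r: float, rho: float) -> float:
    s = 1.0 / rho - 1.0
    al, be = r * s, (1.0 - r) * s
    return float(np.sum(betaln(a + al, n - a + be)) - a.size * betaln(al, be))


def gene_ase_test(hap_a, hap_b, rho: float) -> tuple[float, float]:
    """Beta-binomial LRT for a shared allelic ratio differing from 0.5.

    ``hap_a``/``hap_b`` are per-SNP phased haplotype counts of one gene
    in one individual.  Returns (LR statistic, p) with p from chi2(1).
    At rho = 0 the test reduces exactly to the binomial LRT.
    """
    if rho < 0 or rho >= 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    a = np.asarray(hap_a, float)
    b = np.asarray(hap_b, float)
    n = a + b
    if a.size < 2:
        raise ValueError("need at least two phased SNPs after filtering")
    if rho == 0:
        r_hat = a.sum() / n.sum()
        l1 = _binom_loglik(a, n, r_hat)
        l0 = _binom_loglik(a, n, 0.5)
    else:
        res = minimize_scalar(lambda r: -_bb_loglik(a, n, r, rho),
                              bounds=(1e-9, 1.0 - 1e-9), method="bounded",
                              options={"xatol": 1e-10})
        l1 = -res.fun
        l0 = _bb_loglik(a, n, 0.5, rho)
    lr = max(0.0, 2.0 * (l1 - l0))
    return lr, float(chi2.sf(lr, 1))


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg (step-up) or Holm (step-down) adjustment."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    key = {"BH": "fdr_bh", "Holm": "holm"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}; use 'BH' or 'Holm'")
    return multipletests(p, method=key)[1]


def run_individual_tests(filtered: pd.DataFrame, fallback_rho: float = 0.05,
                         rho_by_individual: dict | None = None
                         ) -> pd.DataFrame:
    """Per (gene, individual, tissue) ASE tests with BH within unit.

    Overdispersion is estimated genome-wide per individual unless
    supplied.  Adjustment is performed within individual x tissue across
    that individual's tested genes.
    """
    results = []
    rho_map = dict(rho_by_individual or {})
    for ind, ind_table in filtered.groupby("individual"):
        rho = rho_map.get(ind)
        if rho is None:
            rho = estimate_overdispersion(ind_table, fallback=fallback_rho)
        for tissue, tis_table in ind_table.groupby("tissue"):
            rows = []
            for gene, gtab in tis_table.groupby("gene", sort=True):
                lr, p = gene_ase_test(gtab["hap_a"], gtab["hap_b"], rho)
                rows.append((gene, ind, tissue, len(gtab),
                             int(gtab["hap_a"].sum()), int(gtab["hap_b"].sum()),
                             rho, lr, p))
            block = pd.DataFrame(rows, columns=[
                "gene", "individual", "tissue", "n_snps", "sum_a", "sum_b",
                "rho", "lr", "p"])
            block["padj"] = adjust_pvalues(block["p"].to_numpy(), "BH")
            results.append(block)
    if not results:
        return pd.DataFrame(columns=["gene", "individual", "tissue", "n_snps",
                                     "sum_a", "sum_b", "rho", "lr", "p", "padj"])
    return pd.concat(results, ignore_index=True)


def population_ase(individual_results: pd.DataFrame, alpha: float = 0.05,
                   min_individuals: int = 2) -> pd.DataFrame:
    """Population-level ASE status per (gene, tissue).

    untested when fewer than ``min_individuals`` individuals were tested;
    ASE when at least two individuals have adjusted p < alpha; non-ASE
    otherwise.
    """
    grouped = individual_results.groupby(["gene", "tissue"])
    summary = grouped.agg(n_tested=("padj", "size"),
                          n_significant=("padj", lambda v: int((v < alpha).sum())))
    status = np.where(summary["n_tested"] < min_individuals, "untested",
                      np.where(summary["n_significant"] >= 2, "ASE", "non-ASE"))
    summary["status"] = status
    return summary.reset_index()


def run_ase(table: pd.DataFrame, species_of: pd.Series | dict,
            min_coverage: int = 10, min_allelic_depth: int = 2,
            min_snps: int = 2, alpha: float = 0.05,
            fallback_rho: float = 0.05):
    """Full ASE chain: filter, test, adjust, population rule per source.

    ``species_of`` maps individual -> source group (collared, pied,
    hybrid); population status is computed within each source group.
    Returns (individual_results, population_by_source) where the latter
    maps source -> DataFrame of per (gene, tissue) statuses.
    """
    species_of = pd.Series(dict(species_of)) \
        if not isinstance(species_of, pd.Series) else species_of
    filtered = filter_snps(table, min_coverage, min_allelic_depth, min_snps)
    indiv = run_individual_tests(filtered, fallback_rho=fallback_rho)
    population = {}
    if len(indiv):
        indiv = indiv.assign(species=species_of.loc[indiv["individual"]]
                             .to_numpy())
        for source, block in indiv.groupby("species"):
            population[source] = population_ase(block, alpha=alpha)
    return indiv, population
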