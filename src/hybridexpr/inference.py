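"""Statistical battery linking expression divergence, ASE, CNEs and
chromosome class.

Mann-Whitney associations between fold-change magnitudes and gene flags,
the continuity-corrected chi-square compensation test (misexpression x
ASE), the hypergeometric fast-Z enrichment test with Holm adjustment
across tissues, and GLM / multiple-linear-regression analyses of the
determinants of expression divergence.  Association analyses are
restricted to autosomal genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, hypergeom, mannwhitneyu

from .ase import adjust_pvalues


@dataclass
class AssociationResult:
    test: str
    statistic: float
    p: float
    direction: int              # sign of median(flagged) - median(unflagged)
    n1: int                     # flagged group size
    n0: int
    tissue: Optional[str] = None
    p_holm: Optional[float] = None
    note: str = ""

    @property
    def testable(self) -> bool:
        return np.isfinite(self.p) if self.p is not None else False


def mwu_association(values, flags, test: str = "mwu",
                    tissue: Optional[str] = None) -> AssociationResult:
    """Two-sided Mann-Whitney U between flagged and unflagged values.

    Exact enumeration when both groups have <= 10 observations and no
    cross-group ties; otherwise the tie-corrected normal approximation.
    An empty group yields an untestable result (p = NaN) rather than an
    error, mirroring how degenerate tables are reported.
    """
    values = np.asarray(values, float)
    flags = np.asarray(flags, bool)
    keep = np.isfinite(values)
    values, flags = values[keep], flags[keep]
    x, y = values[flags], values[~flags]
    if x.size == 0 or y.size == 0:
        return AssociationResult(test=test, statistic=np.nan, p=np.nan,
                                 direction=0, n1=int(x.size), n0=int(y.size),
                                 tissue=tissue, note="untestable: empty group")
    if np.all(values == values[0]):
        # tie-saturated: the rank statistic carries no information
        return AssociationResult(test=test, statistic=x.size * y.size / 2.0,
                                 p=1.0, direction=0, n1=int(x.size),
                                 n0=int(y.size), tissue=tissue)
    exact = (x.size <= 10 and y.size <= 10
             and np.unique(values).size == values.size)
    res = mannwhitneyu(x, y, alternative="two-sided",
                       method="exact" if exact else "asymptotic")
    direction = int(np.sign(np.median(x) - np.median(y)))
    return AssociationResult(test=test, statistic=float(res.statistic),
                             p=float(res.pvalue), direction=direction,
                             n1=int(x.size), n0=int(y.size), tissue=tissue)


def chisq_yates(table) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table.

    The correction term |O - E| - 0.5 is floored at zero; p comes from
    chi2 with one degree of freedom.  Zero marginals are an error.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal: chi-square undefined")
    expected = np.outer(rows, cols) / t.sum()
    corrected = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float((corrected ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, 1))


def hypergeom_enrichment(de_z: int, nde_z: int, de_a: int, nde_a: int
                         ) -> float:
    """One-sided hypergeometric tail P(X >= de_z) for Z-linked DE excess.

    X ~ hypergeometric(N = all genes, K = DE genes, n = Z-linked genes).
    """
    for v in (de_z, nde_z, de_a, nde_a):
        if v < 0:
            raise ValueError("counts must be non-negative")
    N = de_z + nde_z + de_a + nde_a
    if N == 0:
        raise ValueError("empty table")
    K = de_z + de_a
    n = de_z + nde_z
    if de_z > min(K, n):
        raise ValueError("observed count exceeds its marginals")
    return float(hypergeom.sf(de_z - 1, N, K, n))


def fast_z_test(counts_by_tissue: Mapping[str, tuple[int, int, int, int]]
                ) -> pd.DataFrame:
    """Fast-Z enrichment per tissue with Holm adjustment across tissues.

    ``counts_by_tissue`` maps tissue -> (de_z, nde_z, de_a, nde_a); the
    background is the tissue's own expressed, chromosome-assigned genes.
    Tissues with no Z-linked genes are untestable (NaN, excluded from
    the Holm family).
    """
    rows = []
    for tissue, (de_z, nde_z, de_a, nde_a) in counts_by_tissue.items():
        if de_z + nde_z == 0:
            rows.append((tissue, de_z, nde_z, de_a, nde_a, np.nan))
            continue
        rows.append((tissue, de_z, nde_z, de_a, nde_a,
                     hypergeom_enrichment(de_z, nde_z, de_a, nde_a)))
    out = pd.DataFrame(rows, columns=["tissue", "de_z", "nde_z", "de_a",
                                      "nde_a", "p"])
    out["p_holm"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "p_holm"] = adjust_pvalues(
            out.loc[tested, "p"].to_numpy(), "Holm")
    return out


def ase_de_association(de_cp: pd.DataFrame, shrunken_lfc: pd.Series,
                       ase_status_by_source: Mapping[str, pd.Series],
                       chrom_class: pd.Series,
                       tissue: Optional[str] = None) -> list[AssociationResult]:
    """Mann-Whitney association of |shrunken LFC(C/P)| with ASE per source.

    One test per source group (hybrid, collared, pied), on autosomal
    genes whose population ASE status is defined (ASE / non-ASE).
    """
    autosomal = chrom_class.reindex(de_cp.index) == "autosome"
    values_all = shrunken_lfc.reindex(de_cp.index).abs()
    results = []
    for source, status in ase_status_by_source.items():
        status = status.reindex(de_cp.index)
        defined = status.isin(["ASE", "non-ASE"]) & autosomal
        results.append(mwu_association(
            values_all[defined], (status[defined] == "ASE").to_numpy(),
            test=f"ase_de_{source}", tissue=tissue))
    return results


def compensation_test(misexpression: pd.DataFrame, hybrid_ase: pd.Series,
                      chrom_class: pd.Series,
                      tissue: Optional[str] = None) -> AssociationResult:
    """Chi-square association between misexpression and hybrid ASE.

    Restricted to autosomal, CP-conserved (eligible) genes with a
    defined hybrid ASE status.  An empty margin (e.g. no misexpressed
    gene assessable for ASE) yields an untestable "NA" result.
    """
    status = hybrid_ase.reindex(misexpression.index)
    autosomal = chrom_class.reindex(misexpression.index) == "autosome"
    use = misexpression["eligible"] & autosomal \
        & status.isin(["ASE", "non-ASE"])
    mis = misexpression.loc[use, "misexpressed"].to_numpy(bool)
    is_ase = (status[use] == "ASE").to_numpy()
    table = np.array([
        [int((mis & is_ase).sum()), int((mis & ~is_ase).sum())],
        [int((~mis & is_ase).sum()), int((~mis & ~is_ase).sum())],
    ])
    n1, n0 = int(mis.sum()), int((~mis).sum())
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return AssociationResult(test="compensation", statistic=np.nan,
                                 p=np.nan, direction=0, n1=n1, n0=n0,
                                 tissue=tissue, note="NA: empty margin")
    stat, p = chisq_yates(table)
    direction = int(np.sign(table[0, 0] * table[1, 1]
                            - table[0, 1] * table[1, 0]))
    return AssociationResult(test="compensation", statistic=stat, p=p,
                             direction=direction, n1=n1, n0=n0, tissue=tissue)


def glm_determinants(response, covariates: pd.DataFrame,
                     mode: str = "binomial", min_genes: int = 50
                     ) -> pd.DataFrame:
    """Determinants of expression divergence by GLM or linear regression.

    ``mode='binomial'``: logistic regression of the 0/1 DE indicator on
    z-scored covariates (Wald z statistics).  ``mode='linear'``:
    ordinary least squares of |shrunken LFC| (t statistics).  Complete-
    case genes only.
    """
    response = pd.Series(response).astype(float)
    data = covariates.copy()
    data.insert(0, "__y", response.reindex(covariates.index))
    data = data.dropna()
    if len(data) < min_genes:
        raise ValueError(f"only {len(data)} complete-case genes (< {min_genes})")
    y = data.pop("__y").to_numpy()
    X = data.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = data.columns[sd == 0][0]
        raise ValueError(f"covariate {bad!r} is constant: rank deficient")
    X = (X - X.mean(axis=0)) / sd
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if mode == "binomial":
        if len(np.unique(y)) < 2:
            raise ValueError("response is constant; logistic fit undefined")
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    elif mode == "linear":
        fit = sm.OLS(y, design).fit()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not np.all(np.isfinite(fit.bse[1:])) or np.any(np.abs(fit.params[1:]) > 30):
        sep = data.columns[int(np.argmax(np.abs(fit.params[1:])))]
        raise ValueError(f"perfect separation suspected for covariate {sep!r}")
    return pd.DataFrame({
        "covariate": list(data.columns),
        "coef": fit.params[1:],
        "stat": fit.tvalues[1:],
        "p": fit.pvalues[1:],
    })


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tidy table (test, tissue, statistic, p, p_holm, direction, n1, n0)."""
    return pd.DataFrame([{
        "test": r.test, "tissue": r.tissue, "statistic": r.statistic,
        "p": r.p, "p_holm": r.p_holm, "direction": r.direction,
        "n1": r.n1, "n0": r.n0, "note": r.note,
    } for r in results])
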