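"""Negative-binomial differential-expression engine.

Implements the count-based DE workflow on which the downstream analyses
rest: median-of-ratios size factors, gene-wise dispersion estimation with
shrinkage toward a fitted mean-dispersion trend, a per-gene NB log-link
GLM Wald test, normal-prior MAP shrinkage of log2 fold changes, a
log-normalized transform for ordination, and Venn-style DE overlap
counts across tissues.

Fold changes are reported in log2 units as numerator-group over
denominator-group.  Genes with adjusted p below ``alpha`` are DE; genes
that cannot be tested (all-zero counts, non-convergence) are "untested".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

_LN2 = np.log(2.0)
_MIN_DISP = 1e-8
_RIDGE = 1e-6  # weak always-on ridge keeping separated genes finite


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False
                 ) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Reference genes are those with no zero count in any sample; each
    sample's factor is the median over reference genes of count over the
    gene's geometric mean.  No rescaling is applied afterwards.
    """
    k = counts.to_numpy(float)
    all_positive = (k > 0).all(axis=1)
    if not all_positive.any():
        if not pseudo_reference:
            raise ValueError(
                "no gene has all-positive counts; rerun with "
                "pseudo_reference=True to use a positive-count pseudo-reference")
        with np.errstate(divide="ignore"):
            logk = np.where(k > 0, np.log(k), np.nan)
        geo = np.exp(np.nanmean(logk, axis=1))
        usable = np.isfinite(geo) & (geo > 0)
        ratios = k[usable] / geo[usable, None]
        sf = np.array([np.median(col[col > 0]) for col in ratios.T])
        return pd.Series(sf, index=counts.columns, name="size_factor")
    ref = k[all_positive]
    geo = np.exp(np.mean(np.log(ref), axis=1))
    sf = np.median(ref / geo[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _moment_dispersions(norm_counts: np.ndarray, groups: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group method-of-moments dispersion and mean per gene."""
    levels = np.unique(groups)
    ss = np.zeros(norm_counts.shape[0])
    dof = 0
    for lv in levels:
        cols = norm_counts[:, groups == lv]
        if cols.shape[1] >= 2:
            ss += cols.var(axis=1, ddof=1) * (cols.shape[1] - 1)
            dof += cols.shape[1] - 1
    if dof == 0:
        raise ValueError("need >= 2 samples in at least one design group")
    var = ss / dof
    mean = norm_counts.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(mean > 0, (var - mean) / mean ** 2, 0.0)
    return np.maximum(alpha_hat, 0.0), mean


def _fit_trend(alpha_hat: np.ndarray, mean: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by iterated OLS with outlier exclusion."""
    use = (alpha_hat > 0) & (mean > 0)
    if use.sum() < 10:
        a0 = float(np.median(alpha_hat[alpha_hat > 0])) if (alpha_hat > 0).any() \
            else _MIN_DISP
        return max(a0, _MIN_DISP), 0.0
    y = alpha_hat[use]
    x = 1.0 / mean[use]
    keep = np.ones(y.shape, bool)
    a0, a1 = float(np.median(y)), 0.0
    for _ in range(10):
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        beta, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        a0_new, a1_new = max(float(beta[0]), _MIN_DISP), max(float(beta[1]), 0.0)
        fitted = a0_new + a1_new * x
        ratio = y / np.maximum(fitted, _MIN_DISP)
        keep_new = (ratio < 15.0) & (ratio > 1e-4)
        if keep_new.sum() < 10:
            keep_new = keep
        converged = (abs(a0_new - a0) < 1e-8 * max(a0, 1e-8)
                     and np.array_equal(keep_new, keep))
        a0, a1, keep = a0_new, a1_new, keep_new
        if converged:
            break
    return a0, a1


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series,
                         design: pd.Series, prior_var: float = 0.25
                         ) -> pd.Series:
    """Gene-wise NB dispersion with shrinkage toward the fitted trend.

    Method-of-moments estimates on normalized counts within design
    groups are pooled, a trend a0 + a1/mu is fitted by iterative robust
    regression, and the final dispersion is the posterior mode of the
    log dispersion under a normal prior (variance ``prior_var``) centred
    on the log trend.  A single-replicate design falls back to the one
    usable group with a warning.
    """
    groups = design.loc[counts.columns].to_numpy()
    norm_counts = counts.to_numpy(float) / sf.loc[counts.columns].to_numpy()
    levels, sizes = np.unique(groups, return_counts=True)
    if (sizes < 2).all():
        raise ValueError("need >= 2 samples in at least one design group")
    if (sizes < 2).any():
        import logging
        logging.getLogger(__name__).warning(
            "dispersion estimated from %d of %d design groups",
            int((sizes >= 2).sum()), len(levels))
    alpha_hat, mean = _moment_dispersions(norm_counts, groups)
    a0, a1 = _fit_trend(alpha_hat, mean)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mean, 1e-12)
    # sampling variance of the log dispersion estimate; m samples, p groups
    m, p = norm_counts.shape[1], len(levels)
    s2 = float(polygamma(1, max((m - p) / 2.0, 0.5)))
    w_d, w_p = 1.0 / s2, 1.0 / prior_var
    positive = alpha_hat > 0
    log_post = (w_d * np.log(np.maximum(alpha_hat, _MIN_DISP))
                + w_p * np.log(np.maximum(trend, _MIN_DISP))) / (w_d + w_p)
    phi = np.where(positive, np.exp(log_post), np.maximum(trend, _MIN_DISP))
    phi = np.maximum(phi, _MIN_DISP)
    return pd.Series(phi, index=counts.index, name="dispersion")


def _irls_nb(k: np.ndarray, x: np.ndarray, log_sf: np.ndarray,
             phi: np.ndarray, penalty: float = 0.0,
             max_iter: int = 100, tol: float = 1e-8):
    """Vectorized per-gene IRLS for the two-group NB log-link GLM.

    ``k`` is genes x samples, ``x`` the 0/1 group indicator, ``penalty``
    a ridge precision on the group coefficient (natural-log scale).
    Returns (beta0, beta1, se1, converged) on the natural-log scale.
    """
    n_genes = k.shape[0]
    inv_sf = np.exp(-log_sf)
    y = k * inv_sf
    m1 = y[:, x == 1].mean(axis=1)
    m0 = y[:, x == 0].mean(axis=1)
    b0 = np.log(np.maximum(m0, 0.1))
    b1 = np.log(np.maximum(m1, 0.1)) - np.log(np.maximum(m0, 0.1))
    pen = penalty + _RIDGE
    converged = np.zeros(n_genes, bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + log_sf[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - log_sf[None, :]) + (k - mu) / mu
        s0 = w.sum(axis=1)
        s1 = (w * x).sum(axis=1)
        s2 = s1 + pen  # x is 0/1 so sum w x^2 = sum w x
        t0 = (w * z).sum(axis=1)
        t1 = (w * z * x).sum(axis=1)
        det = s0 * s2 - s1 * s1
        det = np.where(det <= 0, np.nan, det)
        b0_new = (s2 * t0 - s1 * t1) / det
        b1_new = (s0 * t1 - s1 * t0) / det
        step = np.maximum(np.abs(b0_new - b0), np.abs(b1_new - b1))
        bad = ~np.isfinite(b0_new) | ~np.isfinite(b1_new)
        b0_new[bad], b1_new[bad] = b0[bad], b1[bad]
        newly = (step < tol) & ~bad
        b0, b1 = b0_new, b1_new
        converged |= newly
        if converged.all():
            break
    eta = b0[:, None] + b1[:, None] * x[None, :] + log_sf[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + phi[:, None] * mu)
    s0 = w.sum(axis=1)
    s1 = (w * x).sum(axis=1)
    det = s0 * s1 - s1 * s1  # information matrix without the ridge
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, s0 / det, np.nan))
    return b0, b1, se1, converged


@dataclass
class Contrast:
    numerator: str
    denominator: str


def wald_test(counts: pd.DataFrame, sf: pd.Series, phi: pd.Series,
              design: pd.Series, contrast: tuple[str, str],
              alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene NB Wald test for one two-group contrast.

    Returns a DataFrame indexed by gene with baseMean, lfc (log2,
    numerator/denominator), se, stat, p, padj (BH over tested genes),
    status in {DE, nDE, untested} and the dispersion used.
    """
    num, den = contrast
    groups = design.loc[counts.columns]
    cols = groups.isin([num, den]).to_numpy()
    if groups.eq(num).sum() == 0 or groups.eq(den).sum() == 0:
        raise ValueError(f"contrast groups {contrast} not both present")
    sub = counts.loc[:, cols]
    x = (groups[cols] == num).to_numpy().astype(float)
    log_sf = np.log(sf.loc[sub.columns].to_numpy(float))
    k = sub.to_numpy(float)
    phi_v = phi.loc[counts.index].to_numpy(float)

    base_mean = (counts.to_numpy(float)
                 / sf.loc[counts.columns].to_numpy(float)).mean(axis=1)
    testable = k.sum(axis=1) > 0
    b0, b1, se1, conv = _irls_nb(k[testable], x, log_sf, phi_v[testable])

    lfc = np.full(counts.shape[0], np.nan)
    se = np.full(counts.shape[0], np.nan)
    stat = np.full(counts.shape[0], np.nan)
    p = np.full(counts.shape[0], np.nan)
    ok = np.zeros(counts.shape[0], bool)
    ok[np.flatnonzero(testable)] = conv & np.isfinite(se1) & (se1 > 0)
    idx = np.flatnonzero(testable)
    lfc[idx] = b1 / _LN2
    se[idx] = se1 / _LN2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat[idx] = b1 / se1
    p[ok] = 2.0 * norm.sf(np.abs(stat[ok]))

    n_failed = int(testable.sum() - (conv & np.isfinite(se1)).sum())
    if n_failed:
        import logging
        logging.getLogger(__name__).warning(
            "%d genes failed to converge in the Wald fit", n_failed)

    padj = np.full(counts.shape[0], np.nan)
    tested = np.isfinite(p)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    status = np.where(~tested, "untested",
                      np.where(padj < alpha, "DE", "nDE"))
    return pd.DataFrame({
        "baseMean": base_mean, "lfc": lfc, "se": se, "stat": stat,
        "p": p, "padj": padj, "status": status, "dispersion": phi_v,
    }, index=counts.index)


def _estimate_lfc_prior_var(result: pd.DataFrame) -> float:
    """Prior variance (natural-log scale) from high-information MLE LFCs."""
    ok = result["status"] != "untested"
    se_ln = result.loc[ok, "se"].to_numpy() * _LN2
    lfc_ln = result.loc[ok, "lfc"].to_numpy() * _LN2
    if se_ln.size == 0:
        return 1.0
    high = se_ln <= np.median(se_ln)
    excess = np.var(lfc_ln[high]) - np.mean(se_ln[high] ** 2)
    return float(np.clip(excess, 1e-3, 100.0))


def shrink_lfc(counts: pd.DataFrame, sf: pd.Series, phi: pd.Series,
               design: pd.Series, contrast: tuple[str, str],
               result: pd.DataFrame, prior_var: float | None = None
               ) -> pd.Series:
    """MAP log2 fold change under a zero-centred normal prior.

    ``prior_var`` (log2 scale) defaults to an estimate from the spread of
    high-information MLE fold changes.  Genes untestable in the Wald fit
    are reported as 0.
    """
    num, den = contrast
    groups = design.loc[counts.columns]
    cols = groups.isin([num, den]).to_numpy()
    sub = counts.loc[:, cols]
    x = (groups[cols] == num).to_numpy().astype(float)
    log_sf = np.log(sf.loc[sub.columns].to_numpy(float))
    k = sub.to_numpy(float)
    phi_v = phi.loc[counts.index].to_numpy(float)
    if prior_var is None:
        pv_ln = _estimate_lfc_prior_var(result)
    else:
        pv_ln = prior_var * _LN2 ** 2
    testable = k.sum(axis=1) > 0
    _, b1, _, _ = _irls_nb(k[testable], x, log_sf, phi_v[testable],
                           penalty=1.0 / pv_ln)
    shrunk = np.zeros(counts.shape[0])
    shrunk[np.flatnonzero(testable)] = b1 / _LN2
    return pd.Series(shrunk, index=counts.index, name="shrunkenLfc")


def rlog_like_transform(counts: pd.DataFrame, sf: pd.Series,
                        pseudo: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudo): monotone, depth-invariant."""
    return np.log2(counts.div(sf.loc[counts.columns], axis=1) + pseudo)


def de_overlap(de_sets: Mapping[str, set], universe: Sequence[str]) -> dict:
    """Exclusive Venn-cell counts of DE genes across tissues.

    Returns a dict mapping a frozenset of tissue names to the number of
    genes DE in exactly those tissues; the empty frozenset holds the
    none-DE count.  All sets must be drawn from ``universe``.
    """
    universe = list(universe)
    uset = set(universe)
    for tissue, genes in de_sets.items():
        extra = set(genes) - uset
        if extra:
            raise ValueError(
                f"DE set for {tissue!r} contains genes outside the "
                f"universe: {sorted(extra)[:5]}")
    cells: dict[frozenset, int] = {}
    tissues = list(de_sets)
    for r in range(len(tissues) + 1):
        for combo in combinations(tissues, r):
            cells[frozenset(combo)] = 0
    for gene in universe:
        member = frozenset(t for t in tissues if gene in de_sets[t])
        cells[member] += 1
    return cells
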