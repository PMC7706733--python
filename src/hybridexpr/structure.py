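"""Expression-level descriptors.

TPM normalization from counts and effective lengths, the Yanai
tissue-specificity index tau with a cross-species consensus, the
expressed-gene census (mean TPM above a threshold), cell-type marker
profiles, PCA with projection of held-out samples, and between-groups
PCA with a Monte-Carlo permutation test on explained inertia.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from counts and per-gene effective lengths.

    Per sample: rate = count / length, TPM = 1e6 * rate / sum(rate).
    Columns of non-degenerate samples sum to 1e6; an all-zero sample
    stays all-zero and is flagged in the log.
    """
    lengths = effective_lengths.reindex(counts.index)
    bad = lengths.isna() | (lengths <= 0)
    if bad.any():
        raise ValueError(
            "zero or missing effective length for genes: "
            f"{list(counts.index[bad][:5])}")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    degenerate = total == 0
    if degenerate.any():
        logger.warning("all-zero samples in TPM: %s",
                       list(counts.columns[degenerate]))
        total = total.replace(0, np.nan)
    out = rate.div(total, axis=1) * 1e6
    return out.fillna(0.0)


def tau(expression_by_tissue: pd.DataFrame, log_transform: bool = True
        ) -> pd.Series:
    """Tissue-specificity index per gene: tau = sum(1 - x_hat) / (n - 1).

    ``expression_by_tissue`` is genes x tissues (mean TPM per tissue).
    Values are log2(x + 1)-damped by default because the index is
    scale-sensitive.  All-zero genes are undefined (NaN) and logged.
    """
    if expression_by_tissue.shape[1] < 2:
        raise ValueError("tau needs at least two tissues")
    x = expression_by_tissue.to_numpy(float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    if log_transform:
        x = np.log2(x + 1.0)
    peak = x.max(axis=1)
    zero = peak == 0
    if zero.any():
        logger.warning("tau undefined for %d all-zero genes", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        x_hat = x / peak[:, None]
    value = (1.0 - x_hat).sum(axis=1) / (x.shape[1] - 1)
    value[zero] = np.nan
    return pd.Series(value, index=expression_by_tissue.index, name="tau")


def consensus_tau(tau_by_species: pd.DataFrame) -> pd.Series:
    """Consensus tissue specificity across species.

    First principal component of the per-species tau vectors (genes as
    observations), sign-fixed to correlate positively with the mean tau,
    min-max rescaled to [0, 1].  Genes with a missing tau are NaN.
    """
    complete = tau_by_species.dropna()
    centred = complete - complete.mean(axis=0)
    _, _, vt = np.linalg.svd(centred.to_numpy(float), full_matrices=False)
    pc1 = centred.to_numpy(float) @ vt[0]
    if np.corrcoef(pc1, complete.mean(axis=1))[0, 1] < 0:
        pc1 = -pc1
    span = pc1.max() - pc1.min()
    scaled = (pc1 - pc1.min()) / span if span > 0 else np.zeros_like(pc1)
    out = pd.Series(np.nan, index=tau_by_species.index, name="consensus_tau")
    out.loc[complete.index] = scaled
    return out


def count_expressed(tpm_matrix: pd.DataFrame, groups: pd.Series,
                    threshold: float = 1.0) -> pd.Series:
    """Number of genes with within-group mean TPM strictly above threshold."""
    out = {}
    for level in pd.unique(groups):
        cols = [c for c in groups.index[groups == level]
                if c in tpm_matrix.columns]
        if len(cols) == 0:
            raise ValueError(f"group {level!r} has no samples in the matrix")
        out[level] = int((tpm_matrix[cols].mean(axis=1) > threshold).sum())
    return pd.Series(out, name="n_expressed")


def marker_profile(tpm_matrix: pd.DataFrame,
                   marker_sets: Mapping[str, Sequence[str]],
                   groups: pd.Series):
    """Within-group mean TPM per marker gene plus per-set medians.

    Returns ``(per_gene, per_set, unmatched)``: marker genes absent from
    the matrix are listed under ``unmatched`` rather than failing.
    """
    levels = list(pd.unique(groups))
    rows, set_rows, unmatched = [], [], {}
    for set_name, genes in marker_sets.items():
        present = [g for g in genes if g in tpm_matrix.index]
        missing = [g for g in genes if g not in tpm_matrix.index]
        if missing:
            unmatched[set_name] = missing
        if not present:
            logger.warning("marker set %r matched no genes", set_name)
            continue
        means = pd.DataFrame({
            level: tpm_matrix.loc[present,
                                  groups.index[groups == level]].mean(axis=1)
            for level in levels})
        means.insert(0, "marker_set", set_name)
        rows.append(means)
        med = means[levels].median(axis=0)
        med["marker_set"] = set_name
        set_rows.append(med)
    per_gene = pd.concat(rows) if rows else pd.DataFrame(
        columns=["marker_set", *levels])
    per_set = pd.DataFrame(set_rows).set_index("marker_set") if set_rows \
        else pd.DataFrame(columns=levels)
    return per_gene, per_set, unmatched


@dataclass
class PcaModel:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # genes x components
    explained_ratio: np.ndarray   # sums to 1 over all components
    center: pd.Series             # per-gene mean used for centering


def pca(matrix: pd.DataFrame, n_components: Optional[int] = None) -> PcaModel:
    """PCA of a samples x genes matrix after gene-wise centering."""
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    center = matrix.mean(axis=0)
    centred = (matrix - center).to_numpy(float)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    k = n_components or len(s)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=matrix.index, columns=comps)
    loadings = pd.DataFrame(vt[:k].T, index=matrix.columns, columns=comps)
    return PcaModel(scores=scores, loadings=loadings,
                    explained_ratio=explained[:k], center=center)


def project_samples(model: PcaModel, new_samples: pd.DataFrame) -> pd.DataFrame:
    """Project held-out samples onto an existing PCA model.

    Projecting a training sample reproduces its original score; the
    projection is linear in the expression profile.
    """
    if not new_samples.columns.equals(model.center.index):
        if set(new_samples.columns) != set(model.center.index):
            raise ValueError("gene universe mismatch with the PCA model")
        new_samples = new_samples[model.center.index]
    centred = (new_samples - model.center).to_numpy(float)
    scores = centred @ model.loadings.to_numpy(float)
    return pd.DataFrame(scores, index=new_samples.index,
                        columns=model.loadings.columns)


@dataclass
class BgPcaResult:
    inertia_pct: float
    p_value: float
    n_perm: int
    observed_by_perm: Optional[np.ndarray] = None


def _inertia_pct(x: np.ndarray, labels: np.ndarray) -> float:
    total = (x ** 2).sum()
    if total == 0:
        return 0.0
    between = 0.0
    for level in np.unique(labels):
        rows = x[labels == level]
        between += rows.shape[0] * (rows.mean(axis=0) ** 2).sum()
    return 100.0 * between / total


def between_group_pca(matrix: pd.DataFrame, labels: pd.Series,
                      n_perm: int = 99,
                      condition_on: Optional[pd.Series] = None,
                      seed: int = 0) -> BgPcaResult:
    """Explained inertia of a grouping factor with a Monte-Carlo test.

    Inertia is the percentage of total (gene-wise centred) variance
    carried by the group means.  With ``condition_on``, profiles are
    first centred within each conditioning level and label permutations
    are restricted within levels, giving the partial (conditional)
    between-groups analysis.  p = (#{perm >= observed} + 1) / (B + 1).
    """
    lab = labels.loc[matrix.index].to_numpy()
    levels, counts_ = np.unique(lab, return_counts=True)
    if len(levels) == 0 or (counts_ == 0).any():
        raise ValueError("every group needs at least one sample")
    # a single group carries no between-group variance: inertia 0 after
    # grand centering, and every permutation ties with the observation
    x = matrix.to_numpy(float)
    if condition_on is not None:
        cond = condition_on.loc[matrix.index].to_numpy()
        x = x.copy()
        for level in np.unique(cond):
            rows = cond == level
            x[rows] -= x[rows].mean(axis=0)
    else:
        cond = None
        x = x - x.mean(axis=0)
    observed = _inertia_pct(x, lab)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for b in range(n_perm):
        permuted = lab.copy()
        if cond is None:
            rng.shuffle(permuted)
        else:
            for level in np.unique(cond):
                rows = np.flatnonzero(cond == level)
                permuted[rows] = permuted[rng.permutation(rows)]
        perms[b] = _inertia_pct(x, permuted)
    p = (np.sum(perms >= observed) + 1.0) / (n_perm + 1.0)
    return BgPcaResult(inertia_pct=float(observed), p_value=float(p),
                       n_perm=n_perm, observed_by_perm=perms)
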