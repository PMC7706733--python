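"""Inheritance-mode classification and misexpression calling.

A gene's mode of expression inheritance in F1 hybrids is read off the
plane of shrunken log2 fold changes x = LFC(hybrid/collared) and
y = LFC(hybrid/pied).  With t = log2(fold_threshold) the six regions
partition the plane:

* |x| < t and |y| < t            -> conserved
* |x| < t and |y| >= t           -> collared_dominant (hybrid tracks collared)
* |x| >= t and |y| < t           -> pied_dominant
* x >= t and y >= t              -> overdominant
* x <= -t and y <= -t            -> underdominant
* opposite signs beyond t        -> additive

Boundary values count as beyond the threshold.  Misexpression is called
on genes conserved between the parents (CP not DE) that are
significantly DE in both hybrid contrasts with sign-consistent fold
changes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("conserved", "additive", "pied_dominant", "collared_dominant",
         "overdominant", "underdominant")


def classify_inheritance(x, y, fold_threshold: float = 1.125):
    """Six-mode classification of (x, y) shrunken LFC pairs.

    Accepts scalars or arrays; NaN input yields "untested".
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    t = np.log2(fold_threshold)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    scalar = x.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    mode = np.full(x.shape, "untested", dtype=object)
    finite = np.isfinite(x) & np.isfinite(y)
    small_x, small_y = np.abs(x) < t, np.abs(y) < t
    mode[finite & small_x & small_y] = "conserved"
    mode[finite & small_x & ~small_y] = "collared_dominant"
    mode[finite & ~small_x & small_y] = "pied_dominant"
    mode[finite & (x >= t) & (y >= t)] = "overdominant"
    mode[finite & (x <= -t) & (y <= -t)] = "underdominant"
    additive = finite & (((x >= t) & (y <= -t)) | ((x <= -t) & (y >= t)))
    mode[additive] = "additive"
    return mode[0] if scalar else mode


def type2_regression(x, y) -> tuple[float, float]:
    """Major-axis (type II) regression through a point cloud.

    Returns (slope, intercept) of the line through the centroid along
    the first eigenvector of the 2x2 covariance of (x, y).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least three finite points")
    cov = np.cov(x, y)
    if np.allclose(cov, 0):
        raise ValueError("zero total variance: major axis undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    if v[0] == 0:
        return float(np.inf), float("nan")
    slope = float(v[1] / v[0])
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def call_misexpression(de_cp: pd.DataFrame, de_hc: pd.DataFrame,
                       de_hp: pd.DataFrame,
                       require_sign_consistency: bool = True) -> pd.DataFrame:
    """Misexpression calls from the three pairwise DE results of one tissue.

    Eligible genes are those conserved between the parents (CP status
    nDE).  A gene is misexpressed when it is eligible and DE in both
    hybrid contrasts; with ``require_sign_consistency`` the two hybrid
    fold changes must share a sign (the over/underdominant geometry).
    Genes untested in any contrast are excluded and counted in the log.
    """
    if not (de_cp.index.equals(de_hc.index) and de_cp.index.equals(de_hp.index)):
        raise ValueError("the three contrasts must share a gene universe")
    tested = ((de_cp["status"] != "untested")
              & (de_hc["status"] != "untested")
              & (de_hp["status"] != "untested"))
    n_excluded = int((~tested).sum())
    if n_excluded:
        logger.info("%d genes untested in at least one contrast excluded",
                    n_excluded)
    cp, hc, hp = de_cp[tested], de_hc[tested], de_hp[tested]
    eligible = cp["status"] == "nDE"
    both_de = (hc["status"] == "DE") & (hp["status"] == "DE")
    same_sign = np.sign(hc["lfc"]) == np.sign(hp["lfc"])
    mis = eligible & both_de
    if require_sign_consistency:
        mis &= same_sign
    direction = np.where(~mis, "none",
                         np.where(hc["lfc"] > 0, "over", "under"))
    return pd.DataFrame({
        "eligible": eligible, "misexpressed": mis, "direction": direction,
    }, index=cp.index)


def inheritance_frequencies(calls: pd.DataFrame,
                            chrom_class: pd.Series) -> pd.DataFrame:
    """Mode frequencies per tissue and chromosome class.

    ``calls`` needs columns gene, tissue, mode; frequencies are over
    classified (non-"untested") genes and sum to 1 per (tissue, class).
    """
    df = calls[calls["mode"] != "untested"].copy()
    missing = ~df["gene"].isin(chrom_class.index)
    if missing.any():
        raise ValueError(
            f"genes without a chromosome class: {list(df['gene'][missing][:5])}")
    df["chrom_class"] = chrom_class.loc[df["gene"]].to_numpy()
    freq = (df.groupby(["tissue", "chrom_class"])["mode"]
            .value_counts(normalize=True).rename("frequency").reset_index())
    # make every mode explicit, including zero-frequency ones
    full = (freq.pivot_table(index=["tissue", "chrom_class"], columns="mode",
                             values="frequency", fill_value=0.0)
            .reindex(columns=list(MODES), fill_value=0.0))
    full.columns.name = None
    return full.reset_index()
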