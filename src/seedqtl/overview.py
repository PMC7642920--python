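"""Transcriptome-level exploratory analyses preceding eQTL mapping.

Centered (unscaled) PCA of the samples, a consecutive-stage fold-change
filter and Ward hierarchical clustering on absolute-Pearson distances.
Stages follow the germination order PD < AR < IM < RP (primary dormant,
after-ripened, six-hour imbibed, radicle protrusion).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

STAGE_ORDER = ("PD", "AR", "IM", "RP")

__all__ = [
    "STAGE_ORDER",
    "pca_variance",
    "consecutive_fold_change_filter",
    "abs_pearson_distance",
    "ward_cluster",
]


def pca_variance(expr: pd.DataFrame, n_components: int | None = None):
    """PCA of samples on gene-centered, unscaled log intensities.

    Each gene is shifted to zero mean across samples; no variance scaling.
    Returns ``(scores, fractions)``: per-sample component scores and the
    fraction of total variance per component (summing to 1).
    """
    if expr.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("zero total variance: identical samples")
    k = min(X.shape) if n_components is None else n_components
    pca = PCA(n_components=min(k, min(X.shape)))
    scores = pca.fit_transform(X)  # PCA centers each gene internally
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    scores = pd.DataFrame(scores, index=expr.columns, columns=cols)
    fractions = pd.Series(pca.explained_variance_ratio_, index=cols)
    return scores, fractions


def _stage_means(expr: pd.DataFrame, design: pd.Series) -> pd.DataFrame:
    missing = [s for s in STAGE_ORDER if s not in set(design)]
    if missing:
        raise ValueError(f"stages absent from the design: {missing}")
    return pd.DataFrame({
        stage: expr.loc[:, design.index[design == stage]].mean(axis=1)
        for stage in STAGE_ORDER
    })


def consecutive_fold_change_filter(
    expr: pd.DataFrame, design: pd.Series, min_fc: float = 2.0,
) -> pd.Index:
    """Genes with a >= ``min_fc`` fold change between some consecutive stages.

    Stage means are taken on the log2 scale, so the criterion is
    |mean(stage_b) - mean(stage_a)| >= log2(min_fc) for at least one of
    PD->AR, AR->IM, IM->RP (boundary inclusive).
    """
    means = _stage_means(expr, design)
    cut = np.log2(min_fc)
    keep = np.zeros(len(expr), dtype=bool)
    for a, b in zip(STAGE_ORDER[:-1], STAGE_ORDER[1:]):
        keep |= (means[b] - means[a]).abs().to_numpy() >= cut
    return expr.index[keep]


def abs_pearson_distance(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Distance ``1 - |Pearson r|`` between rows (or columns) of a matrix.

    Zero-variance vectors get distance 1 to everything else (and 0 to self).
    """
    X = matrix.to_numpy(dtype=float)
    labels = matrix.index
    if axis == "columns":
        X = X.T
        labels = matrix.columns
    if X.shape[1] < 3:
        raise ValueError("need >= 3 observations per vector")
    sd = X.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - np.abs(np.nan_to_num(r, nan=0.0))
    bad = sd == 0
    d[bad, :] = 1.0
    d[:, bad] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(d, index=labels, columns=labels)


def ward_cluster(dist: pd.DataFrame, k: int = 8) -> pd.Series:
    """Cut a Ward-linkage tree of a precomputed distance matrix into k clusters.

    Uses the ward.D2 convention (scipy's ``linkage(..., method="ward")`` on
    the condensed distances).  Agglomeration is deterministic; ties break by
    item order.
    """
    if k > len(dist):
        raise ValueError("k exceeds the number of items")
    condensed = squareform(dist.to_numpy(dtype=float), checks=False)
    Z = linkage(condensed, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=dist.index, name="cluster_id")
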