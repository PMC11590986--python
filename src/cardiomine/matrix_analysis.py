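"""Unsupervised structure in the protein × category score matrix.

PCA projects the eight-dimensional protein score vectors onto a small number
of principal components; columns are mean-centered but not variance-scaled,
since all categories already share the [0, 1] score scale.  Hierarchical
clustering (average linkage by default) groups proteins with similar score
profiles; the pairwise matrix can be reported either as Euclidean distance
or as Pearson correlation (the latter spans [−1, 1] and is the natural scale
for similarity heatmaps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .caseolap import ScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Projections, loadings (categories × k, orthonormal columns), and
    explained-variance ratios of the score-matrix PCA."""

    projections: pd.DataFrame  # proteins x k
    loadings: pd.DataFrame  # categories x k
    explained_variance_ratio: np.ndarray
    mean: pd.Series  # column means removed before the decomposition

    def reconstruct(self) -> pd.DataFrame:
        """Back-project: projections @ loadings.T plus the removed mean."""
        rec = self.projections.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(
            rec + self.mean.to_numpy(), index=self.projections.index,
            columns=self.loadings.index,
        )


def _scoring_frame(scores: ScoreMatrix | pd.DataFrame) -> pd.DataFrame:
    """Rows restricted to proteins with a positive score somewhere."""
    df = scores.score if isinstance(scores, ScoreMatrix) else scores
    return df.loc[df.max(axis=1) > 0]


def pca(scores: ScoreMatrix | pd.DataFrame, k: int = 2) -> PcaResult:
    """PCA of the scoring proteins' score vectors via singular decomposition.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive.  Raises if ``k`` exceeds either matrix dimension.
    """
    X = _scoring_frame(scores)
    n, m = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 scoring proteins")
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds matrix dimensions {X.shape}")
    mean = X.mean(axis=0)
    Xc = X.to_numpy() - mean.to_numpy()
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # flip each component so its dominant loading is positive
    for j in range(Vt.shape[0]):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        projections=pd.DataFrame((U[:, :k] * s[:k]), index=X.index, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k].T, index=X.columns, columns=comp_names),
        explained_variance_ratio=ratio[:k],
        mean=mean,
    )


@dataclass
class ClusterResult:
    """Agglomerative merge tree plus leaf order and a pairwise matrix."""

    linkage_tree: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]
    pairwise: pd.DataFrame  # distance (euclidean) or correlation value
    metric: str


def hierarchical_cluster(
    scores: ScoreMatrix | pd.DataFrame,
    metric: str = "euclidean",
    linkage_method: str = "average",
) -> ClusterResult:
    """Cluster scoring proteins by their score profiles.

    ``metric="euclidean"`` reports pairwise distances (zero diagonal);
    ``metric="correlation"`` reports the Pearson correlation value in [−1, 1]
    (unit diagonal) while clustering on 1 − r.  A constant score profile has
    no defined correlation; such pairs are recorded as 0 with a warning.
    """
    X = _scoring_frame(scores)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 scoring proteins")
    A = X.to_numpy(dtype=float)
    if metric == "euclidean":
        dvec = pdist(A, metric="euclidean")
        pairwise = pd.DataFrame(squareform(dvec), index=X.index, columns=X.index)
    elif metric == "correlation":
        sd = A.std(axis=1)
        constant = sd == 0
        if constant.any():
            logger.warning(
                "%d constant score profile(s); their correlations recorded as 0",
                int(constant.sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(A)
        corr = np.where(np.isfinite(corr), corr, 0.0)
        np.fill_diagonal(corr, 1.0)
        pairwise = pd.DataFrame(corr, index=X.index, columns=X.index)
        dvec = squareform(1.0 - corr, checks=False)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = linkage(dvec, method=linkage_method)
    order = [X.index[i] for i in leaves_list(Z)]
    return ClusterResult(linkage_tree=Z, leaf_order=order, pairwise=pairwise, metric=metric)
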