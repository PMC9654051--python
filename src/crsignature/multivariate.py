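"""Multivariate views of the per-tissue fold-change matrix.

Principal component analysis is run on the correlation matrix of the tissue
columns (so tissues with different fold-change scales contribute equally),
and agglomerative clustering of the tissue columns reports each merge as a
percent similarity, 100 * (1 - d / d_max), with d_max the final merge
distance — the convention used by common commercial statistics packages, so
the last merge is at exactly 0% similarity and identical columns merge at
100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

LINKAGES = ("single", "complete", "average")


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components (eigenvectors)
    scores: pd.DataFrame  # observations x components
    explained: pd.Series  # explained-variance fractions, descending

    def explained_by(self, n: int) -> float:
        """Cumulative explained-variance fraction of the first n components."""
        return float(self.explained.iloc[:n].sum())


def pca_correlation(m: pd.DataFrame) -> PCAResult:
    """PCA via eigendecomposition of the column correlation matrix.

    Rows are observations (genes), columns variables (tissues). Columns are
    standardised before scoring; a constant column has no defined correlation
    and is an error. The sign of each eigenvector is fixed so its
    largest-magnitude loading is positive.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if m.isna().any().any():
        raise ValueError("fold-change matrix contains missing entries")
    sd = m.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    corr = np.corrcoef(m.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)  # clip tiny negative roundoff
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    z = (m - m.mean(axis=0)) / sd
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=m.columns, columns=comps),
        scores=pd.DataFrame(z.to_numpy() @ eigvec, index=m.index, columns=comps),
        explained=pd.Series(eigval / eigval.sum(), index=comps, name="explained"),
    )


def cluster_similarity(m: pd.DataFrame, linkage: str = "complete") -> pd.DataFrame:
    """Agglomerative clustering of columns with percent-similarity merges.

    Euclidean distance between tissue columns; returns one row per merge with
    the two merged cluster ids (scipy convention: ids < n_cols are leaves),
    the merge distance, and similarity = 100 * (1 - d / d_max). Similarities
    are non-increasing for the monotone linkages offered here.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if m.shape[1] < 2:
        raise ValueError("need at least two columns to cluster")
    if m.isna().any().any():
        raise ValueError("fold-change matrix contains missing entries")
    X = m.to_numpy().T  # columns as observations
    Z = hierarchy.linkage(pdist(X), method=linkage)
    d_max = Z[-1, 2]
    sim = 100.0 * (1.0 - Z[:, 2] / d_max) if d_max > 0 else np.full(len(Z), 100.0)
    out = pd.DataFrame(
        {
            "cluster_a": Z[:, 0].astype(int),
            "cluster_b": Z[:, 1].astype(int),
            "distance": Z[:, 2],
            "similarity_pct": sim,
            "n_members": Z[:, 3].astype(int),
        }
    )
    out.attrs["labels"] = list(m.columns)
    return out
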