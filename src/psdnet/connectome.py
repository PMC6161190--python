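"""Correlation of regional protein abundance with the mesoscale connectome.

The connectome is a region x region matrix of projection volumes.  Its
connectivity vector is the row-wise mean including the self-projection
diagonal.  Each protein's per-region mean abundance is correlated
(Pearson) with that vector; proteins with ``r^2`` at or above a
threshold (default 0.6) are "connectivity-correlated".  The Fisher
z-transform ``atanh(r)`` is reported alongside raw r so either scale can
be visualised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from psdnet.signatures import hierarchical_cluster

__all__ = ["connectivity_vector", "correlate_proteins", "correlation_cluster"]

_R_CLIP = 1.0 - 1e-12


def connectivity_vector(matrix: pd.DataFrame) -> pd.Series:
    """Mean voxel sum per region over all targets, itself included."""
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"connectome matrix must be square, got {matrix.shape}")
    if matrix.isna().to_numpy().any():
        raise ValueError("connectome matrix contains missing values")
    return matrix.mean(axis=1)


def correlate_proteins(
    region_means: pd.DataFrame,
    vector: pd.Series,
    r2_threshold: float = 0.6,
) -> pd.DataFrame:
    """Per-protein Pearson correlation with the connectivity vector.

    Parameters
    ----------
    region_means : DataFrame, proteins x regions
        Mean raw abundance per region (brains pooled).
    vector : Series indexed by region
    r2_threshold : float
        Selection cut on r^2; the selected set shrinks monotonically as
        the threshold rises.

    Returns a DataFrame with columns ``protein_id, r, r2, z, constant,
    selected``.  Proteins with a constant regional profile have no
    defined correlation: they are flagged and never selected.
    """
    regions = [r for r in region_means.columns]
    if len(regions) < 3:
        raise ValueError("need >= 3 regions for a meaningful correlation")
    v = vector.reindex(regions).to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError("connectivity vector does not cover all abundance regions")
    if np.ptp(v) == 0:
        raise ValueError("connectivity vector is constant; correlation undefined")
    X = region_means.to_numpy(dtype=float)
    xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sv = np.sqrt((vc**2).sum())
    constant = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ vc) / (sx * sv)
    r = np.where(constant, np.nan, np.clip(r, -1.0, 1.0))
    r2 = r**2
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    selected = np.where(constant, False, r2 >= r2_threshold)
    return pd.DataFrame(
        {
            "protein_id": region_means.index,
            "r": r,
            "r2": r2,
            "z": z,
            "constant": constant,
            "selected": selected,
        }
    ).reset_index(drop=True)


def correlation_cluster(region_means: pd.DataFrame, matrix: pd.DataFrame) -> dict:
    """Region-level abundance-connectivity correlation, clustered.

    Each region i has an *abundance-similarity profile*: the Pearson
    correlation (over proteins) of its abundance column with every
    region's column.  Each region j has a *projection profile*: its row
    of the connectome matrix.  Entry (i, j) of the result is the Pearson
    correlation, over the shared region axis, of region i's similarity
    profile with region j's projection profile — high on the diagonal
    when molecular similarity tracks anatomical connectivity.

    The matrix is then hierarchically clustered on its rows (reusing the
    signature-clustering defaults).  Returns a dict with ``matrix``
    (region x region DataFrame), ``linkage`` and ``order`` (clustered
    region order).
    """
    vec = connectivity_vector(matrix)
    if np.ptp(vec.to_numpy(dtype=float)) == 0:
        raise ValueError("connectivity vector is constant; correlation undefined")
    regions = list(region_means.columns)
    X = region_means[regions].to_numpy(dtype=float)
    M = matrix.reindex(index=regions, columns=regions).to_numpy(dtype=float)
    S = np.corrcoef(X.T)  # region x region abundance similarity
    R = len(regions)
    corr = np.empty((R, R))
    for i in range(R):
        for j in range(R):
            corr[i, j] = np.corrcoef(S[i], M[j])[0, 1]
    out = pd.DataFrame(corr, index=regions, columns=regions)
    clust = hierarchical_cluster(out, zscore_rows=False)
    order = [regions[i] for i in clust["row_order"]]
    return {"matrix": out, "linkage": clust["row_linkage"], "order": order}
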