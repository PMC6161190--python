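"""Regional signatures: differential stability, co-abundance modules, Circos links.

Differential stability (DS, also "avgCor") asks whether a protein's
regional abundance pattern is reproducible between individual animals:
for each protein, the Pearson correlation of its region-profile vectors
is computed for every pair of brains and averaged.  DS near 1 means the
regional pattern is conserved across individuals; DS near 0 means the
pattern is idiosyncratic noise.

Co-abundance modules (postsynaptic proteome modules, PPMs) come from
agglomerative hierarchical clustering of the protein x region mean
abundance matrix (rows Z-scored, Euclidean distance, complete linkage —
the classic heatmap defaults); the number of modules K is chosen by
majority vote of three internal validity indices (silhouette,
Calinski-Harabasz, Dunn) over dendrogram cuts.

Circos link tables express how module proteins are shared between
regions: a protein "positive" in several regions links those regions,
and link widths are fractions of each source region's positive proteome.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score, silhouette_score

__all__ = [
    "differential_stability",
    "select_high_ds",
    "hierarchical_cluster",
    "cut_dendrogram",
    "choose_k",
    "circos_links",
    "linkage_to_newick",
    "replicate_diagnostics",
]


def differential_stability(tensor) -> pd.DataFrame:
    """Average pairwise Pearson correlation of per-brain region profiles.

    For a protein measured in B brains over R regions, all C(B, 2) brain
    pairs contribute a Pearson coefficient between the two R-vectors;
    DS is their mean.  A pair where either brain's profile is constant
    has an undefined correlation: that pair is skipped, ``n_pairs``
    decremented, and the protein flagged.

    Returns a DataFrame with columns ``protein_id, avg_cor, n_pairs,
    flagged``.
    """
    P, R, B = tensor.shape
    if B < 2:
        raise ValueError("differential stability needs >= 2 brains")
    if R < 3:
        raise ValueError("differential stability needs >= 3 regions")
    x = tensor.intensities  # (P, R, B)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))  # (P, B)
    rows = []
    pairs = list(itertools.combinations(range(B), 2))
    # vectorised over proteins: corr(p, b1, b2)
    for i, prot in enumerate(tensor.proteins):
        cors = []
        skipped = False
        for b1, b2 in pairs:
            denom = norms[i, b1] * norms[i, b2]
            if denom == 0:
                skipped = True
                continue
            cors.append(float(xc[i, :, b1] @ xc[i, :, b2] / denom))
        rows.append(
            {
                "protein_id": prot,
                "avg_cor": float(np.mean(cors)) if cors else np.nan,
                "n_pairs": len(cors),
                "flagged": skipped,
            }
        )
    return pd.DataFrame(rows)


def select_high_ds(records: pd.DataFrame, cutoff: float | None = None) -> set:
    """Proteins whose DS meets the cutoff.

    ``cutoff=None`` uses the median avg_cor, splitting the proteome into
    a "high-DS" half with reproducible regional patterns.
    """
    avg = records["avg_cor"]
    if cutoff is None:
        cutoff = float(avg.median())
    return set(records.loc[avg >= cutoff, "protein_id"])


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
    zscore_rows: bool = True,
) -> dict:
    """Agglomerative clustering of rows and columns of an abundance matrix.

    Rows (proteins) are Z-scored before clustering when ``zscore_rows``
    is set — regional *pattern*, not absolute level, drives the modules;
    columns (regions) are clustered on the same Z-scored matrix.
    Returns ``row_linkage``, ``col_linkage``, ``row_order``,
    ``col_order`` and the matrix actually clustered (``scaled``).
    """
    X = matrix.to_numpy(dtype=float)
    if zscore_rows:
        sd = X.std(axis=1, ddof=1, keepdims=True)
        mu = X.mean(axis=1, keepdims=True)
        X = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    scaled = pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
    if X.shape[0] > 1:
        row_linkage = hierarchy.linkage(X, method=method, metric=metric)
        row_order = list(hierarchy.leaves_list(row_linkage))
    else:
        row_linkage, row_order = None, [0]
    if X.shape[1] > 1:
        col_linkage = hierarchy.linkage(X.T, method=method, metric=metric)
        col_order = list(hierarchy.leaves_list(col_linkage))
    else:
        col_linkage, col_order = None, [0]
    return {
        "row_linkage": row_linkage,
        "col_linkage": col_linkage,
        "row_order": row_order,
        "col_order": col_order,
        "scaled": scaled,
    }


def cut_dendrogram(linkage: np.ndarray, k: int, index) -> pd.Series:
    """Cut a linkage at K clusters; labels renumbered 1..K by first appearance."""
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    seen: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in seen:
            seen[r] = len(seen) + 1
        labels.append(seen[r])
    return pd.Series(labels, index=index, name="module")


def _dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min between-cluster distance / max within-cluster diameter."""
    clusters = np.unique(labels)
    max_diam = 0.0
    min_sep = np.inf
    for c in clusters:
        idx = np.nonzero(labels == c)[0]
        if len(idx) > 1:
            max_diam = max(max_diam, dist[np.ix_(idx, idx)].max())
    for c1, c2 in itertools.combinations(clusters, 2):
        i1 = np.nonzero(labels == c1)[0]
        i2 = np.nonzero(labels == c2)[0]
        min_sep = min(min_sep, dist[np.ix_(i1, i2)].min())
    if max_diam == 0:
        return np.inf
    return float(min_sep / max_diam)


def choose_k(
    matrix: pd.DataFrame,
    k_range: tuple[int, int] = (2, 10),
    metric: str = "euclidean",
    method: str = "complete",
    zscore_rows: bool = True,
) -> dict:
    """Pick the number of modules by majority vote of internal indices.

    Over dendrogram cuts K in ``k_range``, computes silhouette,
    Calinski-Harabasz and Dunn; each index votes for its best K and the
    K with most votes wins (ties broken toward the smallest K).
    Returns ``K``, ``votes``, ``scores`` (DataFrame) and the linkage.
    """
    lo, hi = k_range
    n = len(matrix)
    if lo < 2:
        raise ValueError("k_range must start at >= 2")
    hi = min(hi, n - 1)
    if hi < lo:
        raise ValueError(f"k_range {k_range} infeasible for {n} rows")
    clust = hierarchical_cluster(matrix, metric=metric, method=method, zscore_rows=zscore_rows)
    X = clust["scaled"].to_numpy()
    if np.allclose(X, X[0]):
        raise ValueError("degenerate matrix: all rows identical after scaling")
    linkage = clust["row_linkage"]
    dist = squareform(pdist(X, metric=metric))
    rows = []
    for k in range(lo, hi + 1):
        labels = cut_dendrogram(linkage, k, matrix.index).to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        rows.append(
            {
                "K": k,
                "silhouette": silhouette_score(X, labels, metric=metric),
                "calinski_harabasz": calinski_harabasz_score(X, labels),
                "dunn": _dunn_index(dist, labels),
            }
        )
    scores = pd.DataFrame(rows)
    votes: dict[int, int] = {}
    for col in ("silhouette", "calinski_harabasz", "dunn"):
        best_k = int(scores.loc[scores[col].idxmax(), "K"])
        votes[best_k] = votes.get(best_k, 0) + 1
    top = max(votes.values())
    K = min(k for k, v in votes.items() if v == top)
    return {"K": K, "votes": votes, "scores": scores, "linkage": linkage, "clustering": clust}


def circos_links(
    modules: pd.Series,
    region_presence: pd.DataFrame,
) -> pd.DataFrame:
    """Between-region link table for Circos plots.

    ``modules`` maps protein -> module id; ``region_presence`` is a
    protein x region boolean mask of "positive abundance" (in practice:
    above-average regions of the Z-scored profile).  A protein positive
    in k > 1 regions contributes weight ``1/(k-1)`` to each unordered
    pair of its positive regions, so the widths emitted for any source
    region sum to at most 1.  Width of link (A, B, module) is the summed
    contribution of that module's proteins positive in both A and B,
    divided by the number of proteins positive in A (the row region).

    Returns a DataFrame: ``region_a, region_b, module, n_proteins,
    width`` with region_a preceding region_b in column order.
    """
    common = modules.index.intersection(region_presence.index)
    if len(common) != len(modules) or len(common) != len(region_presence):
        raise ValueError("module assignment and presence mask must share protein ids")
    regions = list(region_presence.columns)
    mask = region_presence.to_numpy(dtype=bool)
    n_pos = mask.sum(axis=1)
    pos_per_region = mask.sum(axis=0)
    mod = modules.reindex(region_presence.index).to_numpy()
    rows = []
    for ia, ib in itertools.combinations(range(len(regions)), 2):
        both = mask[:, ia] & mask[:, ib] & (n_pos > 1)
        if not both.any():
            continue
        for m in sorted(pd.unique(mod[both])):
            sel = both & (mod == m)
            if not sel.any():
                continue
            contrib = (1.0 / (n_pos[sel] - 1)).sum()
            rows.append(
                {
                    "region_a": regions[ia],
                    "region_b": regions[ib],
                    "module": m,
                    "n_proteins": int(sel.sum()),
                    "width": contrib / pos_per_region[ia] if pos_per_region[ia] else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["region_a", "region_b", "module", "n_proteins", "width"])


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def replicate_diagnostics(tensor) -> dict:
    """Thin replicate-poolability summary: PCA scores and Tukey HSD.

    Purely descriptive — PCA of per-brain ArcSinH profiles and Tukey's
    honest significant difference across brains — used to judge whether
    individual animals can be pooled.  Not part of the analysis chain.
    """
    from sklearn.decomposition import PCA
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    from psdnet.quantify import arcsinh_transform

    P, R, B = tensor.shape
    x = arcsinh_transform(tensor.intensities)  # (P, R, B)
    flat = x.reshape(P * R, B).T  # brains x (protein*region)
    pca = PCA(n_components=min(3, B), random_state=0)
    scores = pca.fit_transform(flat)
    values = x.mean(axis=1).T.ravel()  # per-brain protein means
    groups = np.repeat(tensor.replicates, P)
    tukey = pairwise_tukeyhsd(values, groups)
    return {
        "pca_scores": pd.DataFrame(
            scores,
            index=tensor.replicates,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        "pca_explained": pca.explained_variance_ratio_,
        "tukey_reject_any": bool(np.any(tukey.reject)),
        "tukey_summary": str(tukey.summary()),
    }
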