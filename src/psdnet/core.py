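"""Cross-region interaction stability and the stable core network.

For every interaction, each region contributes 0 when the two proteins
fall in the same community of that region's partition and 1 when they
fall in different communities; the per-edge sum over R regions is the
stability score (0 = always co-clustered, R = never).  The "stable"
network keeps edges with score <= ``max_score`` (default 2 with R = 7:
co-clustered in at least 5 of 7 regions), is re-clustered with the same
spectral method, and its communities are compared against the
co-abundance modules (PPMs) with one-sided hypergeometric tests.

No label alignment across regions is needed: the score only asks
whether two endpoints are together *within* each region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from psdnet.network import Partition, spectral_partition
from psdnet.quantify import bh_adjust

__all__ = ["StableNetwork", "stability_scores", "select_stable", "module_overlap"]


def stability_scores(
    partitions: dict[str, Partition], edges: list[tuple]
) -> pd.DataFrame:
    """Per-edge count of regions where the endpoints are split apart.

    Returns a DataFrame with columns ``protein_a``, ``protein_b``,
    ``score`` and one 0/1 ``split_<region>`` column per region.
    """
    regions = list(partitions)
    rows = []
    for a, b in edges:
        flags = {}
        for region in regions:
            mem = partitions[region].membership
            if a not in mem or b not in mem:
                missing = a if a not in mem else b
                raise ValueError(
                    f"protein {missing!r} missing from partition of region {region!r}"
                )
            flags[f"split_{region}"] = int(mem[a] != mem[b])
        rows.append({"protein_a": a, "protein_b": b, "score": sum(flags.values()), **flags})
    return pd.DataFrame(rows)


@dataclass
class StableNetwork:
    """Edges stable across regions, with their own clustering."""

    graph: nx.Graph
    partition: Partition | None
    stable_fraction: float
    max_score: int

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def select_stable(
    scores: pd.DataFrame,
    max_score: int = 2,
    weights: dict | None = None,
) -> StableNetwork:
    """Keep edges with stability score <= ``max_score`` and re-cluster.

    With R regions, a retained edge is co-clustered in at least
    ``R - max_score`` regional networks.  ``weights`` optionally maps
    edge tuples to weights used when re-clustering the stable graph
    (unit weights otherwise).
    """
    n_total = len(scores)
    kept = scores[scores["score"] <= max_score]
    g = nx.Graph()
    for a, b in kept[["protein_a", "protein_b"]].itertuples(index=False):
        w = 1.0 if weights is None else weights.get((a, b), weights.get((b, a), 1.0))
        g.add_edge(a, b, weight=w)
    frac = len(kept) / n_total if n_total else 0.0
    if g.number_of_edges() == 0:
        warnings.warn("no edge satisfies the stability cutoff; stable network is empty")
        return StableNetwork(graph=g, partition=None, stable_fraction=frac, max_score=max_score)
    return StableNetwork(
        graph=g,
        partition=spectral_partition(g),
        stable_fraction=frac,
        max_score=max_score,
    )


def module_overlap(
    stable_partition: Partition,
    module_labels: dict[str, int],
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric overlap of stable communities with co-abundance modules.

    For every (community, module) pair with shared universe N, community
    size n, module size K and overlap k, computes the one-sided
    hypergeometric upper-tail probability P(X >= k), BH-adjusted across
    all pairs.  Empty communities or modules give p = 1.
    """
    N = len(universe)
    communities = {
        c: members & universe for c, members in stable_partition.communities().items()
    }
    modules: dict[int, set] = {}
    for prot, m in module_labels.items():
        if prot in universe:
            modules.setdefault(m, set()).add(prot)
    rows = []
    for c, cset in sorted(communities.items()):
        for m, mset in sorted(modules.items()):
            k = len(cset & mset)
            n, K = len(cset), len(mset)
            p = 1.0 if n == 0 or K == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append(
                {"community": c, "module": m, "overlap": k, "community_size": n,
                 "module_size": K, "universe": N, "p": min(p, 1.0)}
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    else:
        table["p_adj"] = []
    return table
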