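"""Over-representation analysis on an ontology DAG.

Classic over-representation uses the one-sided hypergeometric upper
tail: drawing a study set of size n from a universe of N proteins of
which K carry a term, the enrichment p-value is P(X >= k) for the
observed overlap k.

The topology-based *elimination Fisher* variant decorrelates nested
terms: terms are tested bottom-up (children before parents, ordered by
the longest path to a root) and whenever a term is significant at
``alpha_elim`` its annotated proteins are removed from all of its
ancestors before those are tested.  A parent whose signal came entirely
from one significant child is thereby tested on what remains — the
child "absorbs" the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats

from psdnet.quantify import bh_adjust

__all__ = [
    "OntologyDAG",
    "propagate_annotations",
    "classic_fisher",
    "elim_fisher",
    "enrich_clusters",
]


@dataclass
class OntologyDAG:
    """Terms connected by is_a edges (child -> parent), rooted and acyclic."""

    terms: dict[str, str]  # id -> name
    parents: dict[str, list]  # id -> parent ids
    _graph: nx.DiGraph = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"is_a parent {p!r} of {child!r} is not a known term")
                g.add_edge(child, p)
        try:
            list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def roots(self) -> list[str]:
        return sorted(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str) -> set:
        """All is_a ancestors of a term (term itself excluded)."""
        return set(nx.descendants(self._graph, term))

    def levels(self) -> dict[str, int]:
        """Longest-path distance of every term to a root (roots = 0)."""
        order = list(nx.topological_sort(self._graph))  # children before parents
        level: dict[str, int] = {}
        for t in reversed(order):  # parents first
            ps = self.parents.get(t, [])
            level[t] = 0 if not ps else 1 + max(level[p] for p in ps)
        return level


def propagate_annotations(dag: OntologyDAG, direct: dict[str, set]) -> dict[str, set]:
    """Close protein annotations over is_a ancestors (true-path rule).

    ``direct`` maps protein -> directly annotated term ids; the result
    adds every ancestor of every annotated term.  Idempotent.
    """
    anc_cache = {t: dag.ancestors(t) for t in dag.terms}
    out: dict[str, set] = {}
    for prot, terms in direct.items():
        closed = set()
        for t in terms:
            if t not in dag.terms:
                raise ValueError(f"unknown term {t!r} annotated to protein {prot!r}")
            closed.add(t)
            closed |= anc_cache[t]
        out[prot] = closed
    return out


def _term_proteins(annotations: dict[str, set]) -> dict[str, set]:
    """Invert protein -> terms into term -> proteins."""
    inv: dict[str, set] = {}
    for prot, terms in annotations.items():
        for t in terms:
            inv.setdefault(t, set()).add(prot)
    return inv


def classic_fisher(k: int, N: int, K: int, n: int) -> float:
    """One-sided hypergeometric upper-tail probability P(X >= k).

    N: universe size, K: term-annotated proteins in the universe,
    n: study-set size, k: observed overlap.  ``K = 0`` or ``k = 0``
    gives p = 1 (P(X >= 0) = 1).
    """
    if k > min(n, K):
        raise ValueError(f"overlap k={k} exceeds min(study n={n}, term K={K})")
    if K == 0 or k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def elim_fisher(
    dag: OntologyDAG,
    annotations: dict[str, set],
    study: set,
    universe: set,
    alpha_elim: float = 0.01,
) -> pd.DataFrame:
    """Elimination-Fisher enrichment over all terms.

    ``annotations`` must already be propagated (see
    :func:`propagate_annotations`).  Terms are processed by decreasing
    level (longest path to a root), ties in lexicographic id order.
    When a term's elimination p falls below ``alpha_elim``, its
    currently annotated proteins are removed from every ancestor's
    annotation set before that ancestor is tested.

    Returns a DataFrame with one row per term: ``term, name, level, k,
    n, K, N, p_classic, p_elim, eliminated`` (count of proteins removed
    from the term by significant descendants), sorted by ``p_elim``.
    """
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    term_prot = {
        t: prots & universe for t, prots in _term_proteins(annotations).items()
    }
    levels = dag.levels()
    order = sorted(dag.terms, key=lambda t: (-levels[t], t))
    N, n = len(universe), len(study)
    removed: dict[str, set] = {t: set() for t in dag.terms}
    rows = []
    for t in order:
        full = term_prot.get(t, set())
        current = full - removed[t]
        k_classic = len(full & study)
        K_classic = len(full)
        k_elim = len(current & study)
        K_elim = len(current)
        p_classic = classic_fisher(k_classic, N, K_classic, n)
        p_elim = classic_fisher(k_elim, N, K_elim, n)
        if p_elim < alpha_elim and current:
            for anc in dag.ancestors(t):
                removed[anc] |= current
        rows.append(
            {
                "term": t,
                "name": dag.terms[t],
                "level": levels[t],
                "k": k_elim,
                "n": n,
                "K": K_elim,
                "N": N,
                "p_classic": p_classic,
                "p_elim": p_elim,
                "eliminated": len(full) - len(current),
            }
        )
    return pd.DataFrame(rows).sort_values(["p_elim", "term"], ignore_index=True)


def enrich_clusters(
    clusters: dict,
    dag: OntologyDAG,
    annotations: dict[str, set],
    universe: set,
    alpha_elim: float = 0.01,
) -> dict:
    """Elimination-Fisher enrichment for every cluster / module.

    ``clusters`` maps cluster id -> protein set (e.g. the communities of
    a partition or the PPM modules).  Study sets are intersected with
    the universe.  Per cluster, BH adjustment is applied across terms on
    the elimination p-values.

    Returns a dict with ``tables`` (cluster id -> DataFrame including
    ``p_adj``) and ``top_terms`` (DataFrame: cluster, term, name,
    p_elim, p_adj for each non-empty cluster's best term).
    """
    tables: dict = {}
    top_rows = []
    propagated = annotations
    for cid in sorted(clusters, key=str):
        study = set(clusters[cid]) & universe
        if not study:
            tables[cid] = pd.DataFrame(
                columns=["term", "name", "level", "k", "n", "K", "N",
                         "p_classic", "p_elim", "eliminated", "p_adj"]
            )
            continue
        table = elim_fisher(dag, propagated, study, universe, alpha_elim=alpha_elim)
        table["p_adj"] = bh_adjust(table["p_elim"].to_numpy())
        tables[cid] = table
        best = table.iloc[0]
        top_rows.append(
            {
                "cluster": cid,
                "term": best["term"],
                "name": best["name"],
                "p_elim": best["p_elim"],
                "p_adj": best["p_adj"],
            }
        )
    return {"tables": tables, "top_terms": pd.DataFrame(top_rows)}
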