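"""Molecular-complex detection (MCODE) and gene-set enrichment.

MCODE finds densely connected regions of the PPI layer in three stages:

1. *Vertex weighting* — every node is scored by the density of the
   highest k-core of its closed neighbourhood (the node plus its
   neighbours) multiplied by that core's order k; nodes below the degree
   cutoff score 0.
2. *Complex prediction* — starting from the highest-weighted unassigned
   node, neighbours are recursively included when their weight is within
   ``node_score_cutoff`` of the seed's weight, never revisiting nodes
   already assigned to a complex.
3. *Post-processing* — complexes without a k_core-core are discarded; the
   haircut removes (in a single pass) members with within-complex degree
   below 2.  Complexes are ranked by score = density x size.

Tie-breaks are deterministic (lexicographically smallest node id seeds
first, neighbours visited in sorted order) so output is independent of
input ordering and node relabeling.

Enrichment of gene sets (GMT collections) is by the hypergeometric upper
tail, i.e. a one-sided Fisher exact test, with a BH-adjusted column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .network import MiRPPIN

__all__ = ["MCODEParams", "ModuleCluster", "mcode", "EnrichmentRow", "fisher_enrichment"]


@dataclass(frozen=True)
class MCODEParams:
    """Cytoscape-plugin default thresholds."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    iterative_haircut: bool = False


@dataclass
class ModuleCluster:
    rank: int
    seed: str
    members: frozenset[str]
    n_edges: int
    density: float
    score: float  # density x size

    @property
    def size(self) -> int:
        return len(self.members)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _vertex_weights(graph: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree[v] < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(set(graph.neighbors(v)) | {v})
        core_num = nx.core_number(nbhd)
        k_max = max(core_num.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_sub = nbhd.subgraph([u for u, k in core_num.items() if k >= k_max])
        weights[v] = k_max * _density(core_sub)
    return weights


def _grow_complex(
    graph: nx.Graph,
    seed: str,
    weights: Mapping[str, float],
    assigned: set[str],
    node_score_cutoff: float,
    max_depth: int,
) -> set[str]:
    threshold = weights[seed] * (1.0 - node_score_cutoff)
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < max_depth:
        nxt = []
        for v in frontier:
            for u in sorted(graph.neighbors(v)):
                if u in members or u in assigned:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    nxt.append(u)
        frontier = nxt
        depth += 1
    return members


def mcode(net: MiRPPIN, params: MCODEParams = MCODEParams()) -> list[ModuleCluster]:
    """MCODE complexes of the PPI layer, ranked by score (density x size).

    Fluff is disabled by default, so complexes are node-disjoint.  An
    empty PPI layer yields an empty list.
    """
    graph = net.ppi_graph()
    if graph.number_of_nodes() == 0:
        return []
    weights = _vertex_weights(graph, params.degree_cutoff)

    assigned: set[str] = set()
    raw_complexes: list[tuple[str, set[str]]] = []
    # Seed order: weight descending, id ascending — deterministic.
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned or weights[seed] <= 0.0:
            continue
        members = _grow_complex(
            graph, seed, weights, assigned, params.node_score_cutoff, params.max_depth
        )
        assigned |= members
        raw_complexes.append((seed, members))

    clusters: list[ModuleCluster] = []
    for seed, members in raw_complexes:
        sub = graph.subgraph(members)
        core_num = nx.core_number(sub)
        if not core_num or max(core_num.values()) < params.k_core:
            continue
        if params.haircut:
            while True:
                drop = {v for v in sub.nodes if sub.degree[v] < 2}
                if not drop:
                    break
                members = set(sub.nodes) - drop
                sub = graph.subgraph(members)
                if not params.iterative_haircut:
                    break
        if sub.number_of_nodes() < 2:
            continue
        clusters.append(
            ModuleCluster(
                rank=0,
                seed=seed,
                members=frozenset(sub.nodes),
                n_edges=sub.number_of_edges(),
                density=_density(sub),
                score=_density(sub) * sub.number_of_nodes(),
            )
        )

    clusters.sort(key=lambda c: (-c.score, -c.size, min(c.members)))
    return [
        ModuleCluster(i + 1, c.seed, c.members, c.n_edges, c.density, c.score)
        for i, c in enumerate(clusters)
    ]


def clusters_to_frame(clusters: Sequence[ModuleCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.rank, c.score, c.size, c.n_edges, c.seed, ",".join(sorted(c.members)))
            for c in clusters
        ],
        columns=["rank", "score", "n_nodes", "n_edges", "seed", "members"],
    )


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    overlap: int
    query_size: int
    term_size: int
    background_size: int
    p_value: float
    p_adj: float


def fisher_enrichment(
    query: set[str],
    collection: Mapping[str, set[str]],
    background: set[str],
) -> list[EnrichmentRow]:
    """Hypergeometric upper-tail enrichment of ``query`` in each gene set.

    Every term is intersected with the background before testing; the
    query must be a subset of the background.  Rows are sorted by p-value
    (ties by term name) and carry a BH-adjusted column over the tested
    terms.
    """
    if not background:
        raise ValueError("background must be nonempty")
    query = set(query)
    if not query <= set(background):
        raise ValueError("query genes must be a subset of the background")
    n_bg = len(background)
    n_q = len(query)
    rows = []
    for term in sorted(collection):
        members = set(collection[term]) & set(background)
        if not members:
            continue
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K=|term|, n=n_q)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(members), n_q))
        rows.append((term, k, len(members), min(p, 1.0)))
    if not rows:
        return []
    p_adj = bh_adjust([r[3] for r in rows])
    out = [
        EnrichmentRow(
            term=term,
            overlap=k,
            query_size=n_q,
            term_size=t_size,
            background_size=n_bg,
            p_value=p,
            p_adj=float(q),
        )
        for (term, k, t_size, p), q in zip(rows, p_adj)
    ]
    out.sort(key=lambda r: (r.p_value, r.term))
    return out


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term, r.overlap, r.query_size, r.term_size, r.background_size, r.p_value, r.p_adj)
            for r in rows
        ],
        columns=["term", "overlap", "query_size", "term_size", "background_size", "p", "p_adj"],
    )
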