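"""Centrality analysis of the PPI layer and CORE gene classification.

Three classical indices quantify a gene's structural importance in the
PPI layer:

* degree centrality  DC(i) = k, the number of incident PPI edges;
* closeness          CC(i) = N / sum_j d(i, j), with N the number of nodes
  reachable from i (its connected component) and d graph distance;
* betweenness        BC(i) = sum over pairs {x, y}, x != i != y, of the
  fraction of shortest x-y paths passing through i (unnormalised).

Genes whose DC, CC and BC all strictly exceed the network-wide means form
the CORE set — the genes whose targeting boosts a miRNA's priority.

For disconnected networks, closeness uses the component-local node count;
using the global count instead only rescales values within each component
and cannot reorder genes inside a component.  A flag selects the global
convention for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import MiRPPIN

__all__ = [
    "CentralityRecord",
    "compute_centralities",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "core_set",
    "DegreeDistribution",
    "degree_distribution",
]


@dataclass(frozen=True)
class CentralityRecord:
    gene_id: str
    dc: int
    cc: float
    bc: float
    is_core: bool = False


def _require_gene(graph: nx.Graph, gene: str) -> None:
    if gene not in graph:
        raise KeyError(f"gene {gene!r} is not in the PPI layer")


def degree_centrality(net: MiRPPIN, gene: str) -> int:
    """Number of PPI edges incident to ``gene`` (regulatory edges excluded)."""
    graph = net.ppi_graph()
    _require_gene(graph, gene)
    return int(graph.degree[gene])


def closeness_centrality(net: MiRPPIN, gene: str, component_local: bool = True) -> float:
    graph = net.ppi_graph()
    _require_gene(graph, gene)
    return _closeness_map(graph, component_local)[gene]


def _closeness_map(graph: nx.Graph, component_local: bool = True) -> dict[str, float]:
    # networkx returns (n_c - 1) / sum(d); the convention here is N / sum(d),
    # so rescale by N / (n_c - 1) with N component-local or global.
    n_global = graph.number_of_nodes()
    raw = nx.closeness_centrality(graph, wf_improved=False)
    comp_size = {}
    for comp in nx.connected_components(graph):
        for node in comp:
            comp_size[node] = len(comp)
    out = {}
    for node, value in raw.items():
        n_c = comp_size[node]
        if n_c == 1:
            out[node] = 0.0
            continue
        n = n_c if component_local else n_global
        out[node] = value * n / (n_c - 1)
    return out


def betweenness_centrality(net: MiRPPIN) -> dict[str, float]:
    """Unnormalised shortest-path betweenness over unordered pairs."""
    graph = net.ppi_graph()
    return {n: float(v) for n, v in nx.betweenness_centrality(graph, normalized=False).items()}


def compute_centralities(net: MiRPPIN, component_local: bool = True) -> list[CentralityRecord]:
    """Per-gene DC/CC/BC over the PPI layer, with the CORE flag set.

    CORE genes strictly exceed the arithmetic mean of all three indices,
    the means taken over PPI-layer genes only.
    """
    graph = net.ppi_graph()
    if graph.number_of_nodes() == 0:
        return []
    cc = _closeness_map(graph, component_local)
    bc = nx.betweenness_centrality(graph, normalized=False)
    records = [
        CentralityRecord(gene_id=g, dc=int(graph.degree[g]), cc=float(cc[g]), bc=float(bc[g]))
        for g in sorted(graph.nodes)
    ]
    core = core_set(records)
    return [
        CentralityRecord(r.gene_id, r.dc, r.cc, r.bc, is_core=r.gene_id in core)
        for r in records
    ]


def core_set(records: Sequence[CentralityRecord]) -> set[str]:
    """Genes whose DC, CC and BC all strictly exceed their means."""
    if not records:
        return set()
    dc_mean = float(np.mean([r.dc for r in records]))
    cc_mean = float(np.mean([r.cc for r in records]))
    bc_mean = float(np.mean([r.bc for r in records]))
    return {
        r.gene_id
        for r in records
        if r.dc > dc_mean and r.cc > cc_mean and r.bc > bc_mean
    }


def records_to_frame(records: Sequence[CentralityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.dc, r.cc, r.bc, r.is_core) for r in records],
        columns=["gene", "DC", "CC", "BC", "is_core"],
    )


@dataclass
class DegreeDistribution:
    """Empirical degree -> node-fraction table with a log-log OLS slope.

    The slope is fitted by ordinary least squares on (log2 degree,
    log2 fraction) over observed degrees (zero degrees excluded since
    log2(0) is undefined); it is None when fewer than two distinct
    positive degrees are observed.
    """

    degrees: np.ndarray
    fractions: np.ndarray
    slope: float | None
    intercept: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"degree": self.degrees, "fraction": self.fractions})


def _fit_loglog_slope(degrees: np.ndarray, fractions: np.ndarray) -> tuple[float | None, float | None]:
    mask = degrees > 0
    if mask.sum() < 2:
        return None, None
    x = np.log2(degrees[mask].astype(float))
    y = np.log2(fractions[mask])
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def degree_distribution(net: MiRPPIN, layer: str = "PPI") -> DegreeDistribution:
    """Degree distribution of a network layer.

    layer "PPI": gene degree in the PPI layer; layer "REG": miRNA
    out-degree (number of targets) in the regulatory layer.
    """
    if layer == "PPI":
        graph = net.ppi_graph()
        degs = np.array([d for _, d in graph.degree()], dtype=int)
    elif layer == "REG":
        counts: dict[str, int] = {m: 0 for m in net.mirna_nodes}
        for m, _ in net.reg_edges:
            counts[m] += 1
        degs = np.array(list(counts.values()), dtype=int)
    else:
        raise ValueError("layer must be 'PPI' or 'REG'")
    if degs.size == 0:
        return DegreeDistribution(np.array([]), np.array([]), None, None)
    values, counts = np.unique(degs, return_counts=True)
    fractions = counts / degs.size
    slope, intercept = _fit_loglog_slope(values, fractions)
    return DegreeDistribution(values, fractions, slope, intercept)
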