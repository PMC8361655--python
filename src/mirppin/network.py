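"""Construction of the cross-level miRNA-mRNA-PPI network (miR-PPIN).

The condition-specific network has two layers: a directed bipartite
regulatory layer (miRNA -> target gene), obtained by intersecting a
miRNA-target catalog with the differentially expressed miRNA and gene
lists, and an undirected gene-gene PPI layer obtained by restricting a
confidence-filtered STRING-style catalog to the differentially expressed
genes.  Identifiers are canonicalised before any set operation so that
edges are never lost to case or prefix mismatches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "canonical_mirna",
    "canonical_gene",
    "InteractionCatalog",
    "PPICatalog",
    "MiRPPIN",
    "build_bipartite",
    "filter_ppi",
    "build_ppin",
    "merge",
]


def canonical_mirna(name: str) -> str:
    """Canonical mature miRNA name: strip the species prefix, fix case.

    ``hsa-miR-145-5p``, ``MIR-145-5P`` and ``mir-145-5p`` all map to
    ``miR-145-5p``; ``let-7`` family names keep their lowercase form.
    """
    s = str(name).strip()
    low = s.lower()
    if low.startswith("hsa-"):
        s = s[4:]
        low = low[4:]
    if low.startswith("mir-"):
        return "miR-" + s[4:].lower()
    if low.startswith("let-"):
        return "let-" + s[4:].lower()
    return s


def canonical_gene(symbol: str) -> str:
    """Canonical gene symbol: upper-case, stripped."""
    return str(symbol).strip().upper()


@dataclass
class InteractionCatalog:
    """miRNA -> target gene catalog (validated and/or predicted pairs)."""

    edges: set[tuple[str, str]] = field(default_factory=set)
    source_of: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "InteractionCatalog":
        edges: set[tuple[str, str]] = set()
        source_of: dict[tuple[str, str], str] = {}
        for row in pairs:
            m = canonical_mirna(row[0])
            g = canonical_gene(row[1])
            edges.add((m, g))
            if len(row) > 2 and row[2] is not None:
                source_of[(m, g)] = str(row[2])
        return cls(edges=edges, source_of=source_of)

    @classmethod
    def from_tsv(cls, path) -> "InteractionCatalog":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("target catalog needs columns: mirna, gene[, source]")
        return cls.from_pairs(df.itertuples(index=False, name=None))

    def mirnas(self) -> set[str]:
        return {m for m, _ in self.edges}

    def genes(self) -> set[str]:
        return {g for _, g in self.edges}


@dataclass
class PPICatalog:
    """Undirected gene-gene interactions with a combined confidence score.

    Edges are stored under an ordered-pair convention (lexicographically
    smaller symbol first); duplicate rows keep the maximum score.
    ``channels_of`` optionally records the evidence channels supporting an
    edge (e.g. STRING's experiments/database/textmining flags).
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    channels_of: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        a, b = canonical_gene(a), canonical_gene(b)
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, score: float, channels: Iterable[str] | None = None) -> None:
        if canonical_gene(a) == canonical_gene(b):
            return  # self-loops carry no interaction information
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"combined score {score} outside [0, 1]")
        key = self._key(a, b)
        if key not in self.scores or score > self.scores[key]:
            self.scores[key] = score
        if channels is not None:
            prev = self.channels_of.get(key, frozenset())
            self.channels_of[key] = prev | frozenset(channels)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "PPICatalog":
        cat = cls()
        for row in rows:
            channels = None
            if len(row) > 3 and row[3] is not None:
                channels = [c for c in str(row[3]).split(",") if c]
            cat.add(row[0], row[1], float(row[2]), channels)
        return cat

    @classmethod
    def from_tsv(cls, path) -> "PPICatalog":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 3:
            raise ValueError("PPI catalog needs columns: gene_a, gene_b, score[, channels]")
        return cls.from_rows(df.itertuples(index=False, name=None))

    def edges(self) -> set[tuple[str, str]]:
        return set(self.scores)

    def genes(self) -> set[str]:
        return {g for pair in self.scores for g in pair}


@dataclass
class MiRPPIN:
    """Merged two-layer network: directed miRNA->gene + undirected PPI."""

    mirna_nodes: set[str] = field(default_factory=set)
    gene_nodes: set[str] = field(default_factory=set)
    reg_edges: set[tuple[str, str]] = field(default_factory=set)
    ppi_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        collision = self.mirna_nodes & self.gene_nodes
        if collision:
            raise ValueError(f"ids used both as miRNA and gene: {sorted(collision)[:5]}")
        for m, g in self.reg_edges:
            if m not in self.mirna_nodes or g not in self.gene_nodes:
                raise ValueError(f"regulatory edge ({m}, {g}) has endpoint outside node sets")
        for a, b in self.ppi_edges:
            if a not in self.gene_nodes or b not in self.gene_nodes:
                raise ValueError(f"PPI edge ({a}, {b}) has endpoint outside gene nodes")
        targeted = {m for m, _ in self.reg_edges}
        isolated = self.mirna_nodes - targeted
        if isolated:
            raise ValueError(f"miRNA nodes without regulatory edges: {sorted(isolated)[:5]}")

    @property
    def ppi_genes(self) -> set[str]:
        return {g for pair in self.ppi_edges for g in pair}

    def targets(self, mirna: str) -> set[str]:
        return {g for m, g in self.reg_edges if m == mirna}

    def summary(self) -> dict[str, int]:
        return {
            "n_mirnas": len(self.mirna_nodes),
            "n_genes": len(self.gene_nodes),
            "n_reg_edges": len(self.reg_edges),
            "n_ppi_edges": len(self.ppi_edges),
        }

    def ppi_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ppi_genes)
        g.add_edges_from(self.ppi_edges)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(m, g, "REG") for m, g in sorted(self.reg_edges)]
        rows += [(a, b, "PPI") for a, b in sorted(self.ppi_edges)]
        return pd.DataFrame(rows, columns=["source", "target", "layer"])

    def to_tsv(self, path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MiRPPIN":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"source", "target", "layer"}
        if not required.issubset(df.columns):
            raise ValueError(f"network TSV needs columns {sorted(required)}")
        net = cls()
        for src, dst, layer in df[["source", "target", "layer"]].itertuples(index=False):
            if layer == "REG":
                m, g = canonical_mirna(src), canonical_gene(dst)
                net.mirna_nodes.add(m)
                net.gene_nodes.add(g)
                net.reg_edges.add((m, g))
            elif layer == "PPI":
                a, b = canonical_gene(src), canonical_gene(dst)
                key = (a, b) if a <= b else (b, a)
                net.gene_nodes.update(key)
                net.ppi_edges.add(key)
            else:
                raise ValueError(f"unknown layer {layer!r}")
        net.validate()
        return net

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for m in self.mirna_nodes:
            g.add_node(m, kind="miRNA")
        for gene in self.gene_nodes:
            g.add_node(gene, kind="gene")
        for m, t in self.reg_edges:
            g.add_edge(m, t, layer="REG")
        for a, b in self.ppi_edges:
            g.add_edge(a, b, layer="PPI")
            g.add_edge(b, a, layer="PPI")
        nx.write_graphml(g, path)


def build_bipartite(
    de_mirnas: Sequence[str], de_genes: Sequence[str], catalog: InteractionCatalog
) -> MiRPPIN:
    """Condition-specific regulatory layer: catalog edges with a DE miRNA
    and a DE gene at the two endpoints; nodes without surviving edges are
    excluded."""
    mirs = {canonical_mirna(m) for m in de_mirnas}
    genes = {canonical_gene(g) for g in de_genes}
    reg = {(m, g) for m, g in catalog.edges if m in mirs and g in genes}
    if not reg:
        warnings.warn("DE lists and catalog share no edges; regulatory layer is empty")
    return MiRPPIN(
        mirna_nodes={m for m, _ in reg},
        gene_nodes={g for _, g in reg},
        reg_edges=reg,
    )


def filter_ppi(
    catalog: PPICatalog,
    min_score: float = 0.7,
    exclude_channels: frozenset[str] = frozenset({"textmining"}),
) -> PPICatalog:
    """High-confidence PPI subset: combined score >= min_score (non-strict)
    and, when channel flags are present, at least one supporting channel
    outside ``exclude_channels``."""
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be in [0, 1]")
    exclude = frozenset(exclude_channels)
    out = PPICatalog()
    for key, score in catalog.scores.items():
        if score < min_score:
            continue
        channels = catalog.channels_of.get(key)
        if channels is not None and not (channels - exclude):
            continue
        out.scores[key] = score
        if channels is not None:
            out.channels_of[key] = channels
    return out


def build_ppin(de_genes: Sequence[str], filtered: PPICatalog) -> MiRPPIN:
    """PPI layer over the DE genes: filtered catalog edges with both
    endpoints differentially expressed."""
    genes = {canonical_gene(g) for g in de_genes}
    ppi = {key for key in filtered.scores if key[0] in genes and key[1] in genes}
    return MiRPPIN(gene_nodes={g for pair in ppi for g in pair}, ppi_edges=ppi)


def merge(reg_layer: MiRPPIN, ppi_layer: MiRPPIN) -> MiRPPIN:
    """Union of the regulatory and PPI layers (the miR-PPIN).

    Gene nodes are the union of genes in either layer; a gene regulated by
    a miRNA but absent from the PPI layer stays in the network.
    """
    merged = MiRPPIN(
        mirna_nodes=reg_layer.mirna_nodes | ppi_layer.mirna_nodes,
        gene_nodes=reg_layer.gene_nodes | ppi_layer.gene_nodes,
        reg_edges=reg_layer.reg_edges | ppi_layer.reg_edges,
        ppi_edges=reg_layer.ppi_edges | ppi_layer.ppi_edges,
    )
    logger.info("merged network: %s", merged.summary())
    return merged
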