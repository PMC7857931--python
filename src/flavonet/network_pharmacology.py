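"""Compound-target / PPI network construction, centralities and hub filtering.

Putative targets of the annotated compounds form two graphs: a bipartite
compound-target network (used to rank compounds by connectivity) and a
protein-protein interaction (PPI) network whose high-centrality nodes are the
"core targets" taken forward to enrichment.  Centralities follow the
conventions of common network-analysis tools:

* degree: incident edge count (integer);
* betweenness: shortest-path pair counts normalised by (n-1)(n-2)/2 for an
  undirected graph on n nodes;
* closeness: computed within a node's connected component and scaled by
  (|C|-1)/(n-1), so values stay in [0, 1] on disconnected graphs and a
  singleton has closeness 0.

Edge confidence scores are used only for filtering (strictly greater than the
cutoff), never as shortest-path weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "InteractionGraph",
    "CentralityRecord",
    "build_graph",
    "centralities",
    "select_core_targets",
    "rank_compounds",
    "build_tripartite",
    "read_edge_table",
    "write_sif",
    "write_graphml",
]


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    degree: int
    betweenness: float
    closeness: float


class InteractionGraph:
    """A simple undirected graph of typed nodes with optional edge confidence.

    Thin wrapper over :class:`networkx.Graph`; node ``kind`` tags (e.g.
    ``gene``, ``compound``, ``pathway``) are preserved as node attributes so
    exports stay consumable by Cytoscape-style tools.
    """

    def __init__(self) -> None:
        self.g = nx.Graph()
        self.dropped_self_loops = 0
        self.dropped_low_confidence = 0

    def add_node(self, label: str, kind: str = "gene") -> None:
        self.g.add_node(label, kind=kind)

    def add_edge(self, a: str, b: str, confidence: float | None = None,
                 kind_a: str = "gene", kind_b: str = "gene") -> None:
        if a == b:
            self.dropped_self_loops += 1
            return
        if a not in self.g:
            self.add_node(a, kind_a)
        if b not in self.g:
            self.add_node(b, kind_b)
        if self.g.has_edge(a, b):
            old = self.g.edges[a, b].get("confidence")
            if confidence is not None and (old is None or confidence > old):
                self.g.edges[a, b]["confidence"] = confidence
            return
        if confidence is None:
            self.g.add_edge(a, b)
        else:
            self.g.add_edge(a, b, confidence=confidence)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.g.nodes(data=True) if d.get("kind") == kind)


def read_edge_table(path: str | Path) -> list[tuple[str, str, float | None]]:
    """Read a TSV edge list (nodeA, nodeB[, confidence]); '#' lines skipped."""
    rows: list[tuple[str, str, float | None]] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        if parts[0].lower() in ("nodea", "source", "node_a"):
            continue
        conf = float(parts[2]) if len(parts) > 2 and parts[2] not in ("", "-") else None
        rows.append((parts[0], parts[1], conf))
    return rows


def build_graph(
    edge_table: Iterable[tuple[str, str, float | None]],
    min_confidence: float = 0.4,
    uppercase: bool = True,
) -> InteractionGraph:
    """Build a PPI graph keeping edges with confidence strictly > cutoff.

    Unscored edges are kept.  Duplicate rows merge into one edge with the
    maximum confidence; self-loops are dropped (counted on the graph).
    Gene symbols are uppercased on ingestion unless ``uppercase=False``.
    """
    graph = InteractionGraph()
    for a, b, conf in edge_table:
        if uppercase:
            a, b = a.upper(), b.upper()
        if conf is not None and conf <= min_confidence:
            graph.dropped_low_confidence += 1
            continue
        graph.add_edge(a, b, conf)
    return graph


def centralities(graph: InteractionGraph) -> list[CentralityRecord]:
    """Degree, normalised betweenness and component-scaled closeness per node."""
    g = graph.g
    if g.number_of_nodes() == 0:
        return []
    betweenness = nx.betweenness_centrality(g, normalized=True)
    # wf_improved is exactly the (|C|-1)/(n-1) component scaling.
    closeness = nx.closeness_centrality(g, wf_improved=True)
    return [
        CentralityRecord(node, g.degree[node], betweenness[node], closeness[node])
        for node in sorted(g.nodes)
    ]


def select_core_targets(
    records: Sequence[CentralityRecord],
    min_degree: int = 50,
    min_betweenness: float = 0.01,
    min_closeness: float = 0.6,
) -> set[str]:
    """Nodes meeting ALL thresholds (inclusive) -- the core-target filter."""
    return {
        r.node
        for r in records
        if r.degree >= min_degree
        and r.betweenness >= min_betweenness
        and r.closeness >= min_closeness
    }


def rank_compounds(bipartite_graph: InteractionGraph, k: int = 5) -> list[str]:
    """Top-k compounds of a compound-target graph by (degree, betweenness).

    Ties on degree are broken by betweenness (descending), then label.
    ``k`` larger than the number of compounds returns all of them.
    """
    compounds = bipartite_graph.nodes_of_kind("compound")
    betweenness = nx.betweenness_centrality(bipartite_graph.g, normalized=True)
    ranked = sorted(
        compounds,
        key=lambda c: (-bipartite_graph.g.degree[c], -betweenness[c], c),
    )
    return ranked[: max(k, 0)]


def build_tripartite(
    compound_target_edges: Iterable[tuple[str, str]],
    target_pathway_edges: Iterable[tuple[str, str]],
) -> InteractionGraph:
    """Merge compound-gene and gene-pathway edges into one three-kind graph.

    Pathway edges whose gene never occurs in the compound-target layer are
    excluded and counted on ``graph.dropped_dangling``.
    """
    graph = InteractionGraph()
    genes: set[str] = set()
    for compound, gene in compound_target_edges:
        gene = gene.upper()
        genes.add(gene)
        graph.add_edge(compound, gene, kind_a="compound", kind_b="gene")
    dangling = 0
    for gene, pathway in target_pathway_edges:
        gene = gene.upper()
        if gene not in genes:
            dangling += 1
            continue
        graph.add_edge(gene, pathway, kind_a="gene", kind_b="pathway")
    graph.dropped_dangling = dangling
    return graph


def write_sif(graph: InteractionGraph, path: str | Path, interaction: str = "pp") -> None:
    """Export as SIF: ``nodeA<TAB>interaction<TAB>nodeB`` per edge."""
    lines = [f"{a}\t{interaction}\t{b}" for a, b in sorted(graph.g.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_graphml(graph: InteractionGraph, path: str | Path) -> None:
    """Export as GraphML with node-kind attributes (Cytoscape-importable)."""
    nx.write_graphml(graph.g, str(path))
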