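"""Clinician-readable graph renderings and cluster summaries.

Conventions follow the figures the method is read with: similarity-graph
nodes are labelled by utterance position, keyword-graph nodes by keyword;
edges below the weak/strong cutoff are drawn dashed (weak correlation) and
blue, edges at or above it solid black; cross edges between views are
orange. Clusters are the connected components of the strong-edge subgraph;
a cluster is annotated as "filler" when at least half of its member
utterances are conversation fillers ("mhm", "okay", ...) or single-token
back-channels — such clusters are dense but clinically uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .kcg import KeywordGraph, MultiViewKeywordGraph
from .similarity import MultiViewSimilarityGraph, SimilarityGraph

__all__ = ["RenderSpec", "Cluster", "render_graph", "to_dot",
           "detect_clusters", "marker_cluster_report", "read_graphml",
           "DEFAULT_FILLER_VOCABULARY"]

DEFAULT_FILLER_VOCABULARY = (
    "mhm", "uh-huh", "uh", "huh", "okay", "yeah", "right", "sure", "mm",
    "hmm", "yes", "no", "nice", "cool", "awesome",
)


@dataclass(frozen=True)
class RenderSpec:
    weak_strong_cutoff: float = 0.5
    layout: str = "force_directed"  # cosmetic only
    annotate_clusters: bool = True
    filler_vocabulary: tuple = DEFAULT_FILLER_VOCABULARY
    output_format: str = "dot"  # dot | graphml | png | svg

    def __post_init__(self):
        if not -1.0 <= self.weak_strong_cutoff <= 1.0:
            raise ValueError("weak_strong_cutoff must lie in [-1, 1]")


@dataclass
class Cluster:
    nodes: frozenset
    kind: str  # "filler" or "content"


def _as_networkx(graph) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    return graph.to_networkx()


def _edge_style(data: dict, cutoff: float) -> str:
    if data.get("edge_type") == "cross":
        return 'style=solid, color=orange'
    if data.get("weight", 0.0) < cutoff:
        return 'style=dashed, color=blue'
    return 'style=solid, color=black'


def to_dot(graph, spec: RenderSpec = RenderSpec(), texts=None) -> str:
    """Deterministic DOT text for any built graph (nodes sorted by id,
    edges lexicographic)."""
    g = _as_networkx(graph)
    filler_nodes: set = set()
    if spec.annotate_clusters:
        for cluster in detect_clusters(graph, spec, texts=texts):
            if cluster.kind == "filler":
                filler_nodes |= set(cluster.nodes)
    lines = ["graph G {"]
    for n in sorted(g.nodes, key=str):
        attrs = [f'label="{n}"']
        if n in filler_nodes:
            attrs.append("color=red")
        lines.append(f'  "{n}" [{", ".join(attrs)}];')
    for u, v, data in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        style = _edge_style(data, spec.weak_strong_cutoff)
        w = data.get("weight", 1.0)
        lines.append(f'  "{u}" -- "{v}" [{style}, weight={w:.6f}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def render_graph(graph, spec: RenderSpec, path, texts=None) -> Path:
    """Write the graph in the requested format; returns the written path."""
    path = Path(path)
    if spec.output_format == "dot":
        path.write_text(to_dot(graph, spec, texts=texts), encoding="utf-8")
    elif spec.output_format == "graphml":
        nx.write_graphml(_as_networkx(graph), path)
    elif spec.output_format in ("png", "svg"):
        raise RuntimeError(
            "png/svg rendering requires an external graphviz layout engine; "
            "write DOT output and run it through `dot` instead")
    else:
        raise ValueError(f"unknown output format {spec.output_format!r}")
    return path


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def _strong_subgraph(g: nx.Graph, cutoff: float) -> nx.Graph:
    strong = nx.Graph()
    strong.add_nodes_from(g.nodes)
    strong.add_edges_from((u, v) for u, v, d in g.edges(data=True)
                          if d.get("weight", 0.0) >= cutoff)
    return strong


def detect_clusters(graph, spec: RenderSpec = RenderSpec(),
                    texts=None) -> list[Cluster]:
    """Connected components of the strong-edge subgraph, annotated filler or
    content.

    ``texts`` maps a node id to its utterance text; without it (keyword
    graphs) every cluster is "content".
    """
    g = _as_networkx(graph)
    strong = _strong_subgraph(g, spec.weak_strong_cutoff)
    fillers = set(spec.filler_vocabulary)
    clusters = []
    for comp in nx.connected_components(strong):
        kind = "content"
        if texts is not None:
            n_filler = 0
            for n in comp:
                text = texts.get(n, "") if hasattr(texts, "get") else texts[n]
                tokens = text.split()
                if text in fillers or len(tokens) <= 1:
                    n_filler += 1
            if n_filler * 2 >= len(comp):
                kind = "filler"
        clusters.append(Cluster(nodes=frozenset(comp), kind=kind))
    clusters.sort(key=lambda c: sorted(str(n) for n in c.nodes))
    return clusters


def marker_cluster_report(kcg: KeywordGraph | MultiViewKeywordGraph,
                          marker_keywords,
                          spec: RenderSpec = RenderSpec()) -> dict:
    """Which marker keywords appear as nodes, and whether two or more share
    a strong-edge cluster."""
    g = _as_networkx(kcg)

    def base_keyword(node) -> str:
        # multi-view nodes are namespaced "view:keyword"
        return str(node).split(":", 1)[-1]

    markers = set(marker_keywords)
    present = sorted({base_keyword(n) for n in g.nodes} & markers)
    marker_clusters = []
    if present:
        strong = _strong_subgraph(g, spec.weak_strong_cutoff)
        for comp in nx.connected_components(strong):
            in_comp = sorted({base_keyword(n) for n in comp} & markers)
            if len(in_comp) >= 2:
                marker_clusters.append(in_comp)
    return {
        "markers_present": present,
        "marker_clusters": sorted(marker_clusters),
        "has_marker_cluster": bool(marker_clusters),
    }
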