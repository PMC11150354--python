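"""Sentence-similarity graphs.

Baseline form: every utterance is a node, and an undirected edge carries the
cosine similarity of the two sentence embeddings whenever it reaches the
similarity threshold (the threshold is a sparsity hyper-parameter, tuned on
the development split).

Multi-view form: one similarity graph per speaker view, plus *cross edges*
joining each question utterance to each utterance of the patient turn that
answers it. Cross edges come from discourse structure, not similarity, so
they are never thresholded; they carry weight 1.0 and edge_type "cross".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import QAPair, Speaker, Transcript

__all__ = [
    "SimilarityGraph", "MultiViewSimilarityGraph",
    "cosine_matrix", "build_similarity_graph", "build_mv_similarity_graph",
    "cross_edges_from_pairs",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_GRID = (0.3, 0.4, 0.5, 0.6, 0.7)


@dataclass
class SimilarityGraph:
    node_ids: list[int]                    # utterance indices, graph order
    node_features: np.ndarray              # (n, dim) embeddings
    edges: dict[tuple[int, int], float]    # (i, j) with i < j -> cosine weight
    threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency in graph (not utterance) order."""
        pos = {nid: k for k, nid in enumerate(self.node_ids)}
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in self.edges.items():
            a[pos[i], pos[j]] = w
            a[pos[j], pos[i]] = w
        return a

    def to_networkx(self, speaker: str | None = None) -> nx.Graph:
        g = nx.Graph()
        for nid in self.node_ids:
            g.add_node(nid, **({"speaker": speaker} if speaker else {}))
        for (i, j), w in sorted(self.edges.items()):
            g.add_edge(i, j, weight=float(w), edge_type="intra")
        return g


@dataclass
class MultiViewSimilarityGraph:
    therapist_graph: SimilarityGraph
    patient_graph: SimilarityGraph
    cross_edges: set[tuple[int, int]] = field(default_factory=set)  # (t_utt, p_utt)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for nid in self.therapist_graph.node_ids:
            g.add_node(nid, speaker="therapist")
        for nid in self.patient_graph.node_ids:
            g.add_node(nid, speaker="patient")
        for (i, j), w in sorted(self.therapist_graph.edges.items()):
            g.add_edge(i, j, weight=float(w), edge_type="intra_t")
        for (i, j), w in sorted(self.patient_graph.edges.items()):
            g.add_edge(i, j, weight=float(w), edge_type="intra_p")
        for (q, a) in sorted(self.cross_edges):
            g.add_edge(q, a, weight=1.0, edge_type="cross")
        return g


def cosine_matrix(embeddings: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(embeddings, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = embeddings / norms
    return unit @ unit.T


def build_similarity_graph(
    embeddings: np.ndarray,
    threshold: float,
    node_ids: list[int] | None = None,
) -> SimilarityGraph:
    """Complete-thresholded similarity graph over one set of embeddings.

    Edge (i, j), i < j, is retained iff cosine(e_i, e_j) >= threshold and
    carries that cosine as its weight.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2:
        raise ValueError(f"embeddings must be 2-D, got shape {embeddings.shape}")
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [-1, 1]")
    n = embeddings.shape[0]
    ids = list(range(n)) if node_ids is None else list(node_ids)
    if len(ids) != n:
        raise ValueError("node_ids length must match embeddings")
    edges: dict[tuple[int, int], float] = {}
    if n > 1:
        sim = cosine_matrix(embeddings)
        iu, ju = np.triu_indices(n, k=1)
        keep = sim[iu, ju] >= threshold
        for i, j in zip(iu[keep], ju[keep]):
            edges[(ids[i], ids[j])] = float(sim[i, j])
    return SimilarityGraph(node_ids=ids, node_features=embeddings,
                           edges=edges, threshold=threshold)


def cross_edges_from_pairs(qapairs: list[QAPair]) -> set[tuple[int, int]]:
    """Expand turn-level question-answer pairs to utterance-level edges:
    every utterance of the question turn connects to every utterance of the
    answer turn."""
    edges: set[tuple[int, int]] = set()
    for pair in qapairs:
        for q in pair.question_turn.utterance_indices:
            for a in pair.answer_turn.utterance_indices:
                edges.add((q, a))
    return edges


def build_mv_similarity_graph(
    transcript: Transcript,
    embeddings: np.ndarray,
    qapairs: list[QAPair],
    threshold_t: float,
    threshold_p: float | None = None,
) -> MultiViewSimilarityGraph:
    """Multi-view similarity graph: per-view thresholded subgraphs plus
    un-thresholded question-answer cross edges."""
    if threshold_p is None:
        threshold_p = threshold_t
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.shape[0] != len(transcript.utterances):
        raise ValueError("embeddings must cover every utterance")
    t_ids = [u.index for u in transcript.utterances if u.speaker is Speaker.THERAPIST]
    p_ids = [u.index for u in transcript.utterances if u.speaker is Speaker.PATIENT]
    for name, ids in (("therapist", t_ids), ("patient", p_ids)):
        if not ids:
            log.warning("transcript %s: empty %s view", transcript.id, name)
    t_graph = build_similarity_graph(
        embeddings[t_ids] if t_ids else np.zeros((0, embeddings.shape[1])),
        threshold_t, node_ids=t_ids)
    p_graph = build_similarity_graph(
        embeddings[p_ids] if p_ids else np.zeros((0, embeddings.shape[1])),
        threshold_p, node_ids=p_ids)
    return MultiViewSimilarityGraph(
        therapist_graph=t_graph,
        patient_graph=p_graph,
        cross_edges=cross_edges_from_pairs(qapairs),
    )
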