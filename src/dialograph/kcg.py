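"""Keyword correlation graphs (KCG).

An NMF topic model is fitted over the *training-split* sentences, each
sentence treated as one document of a TF-IDF sentence-term matrix. For a
given transcript, word importance is the transcript's topic loading (a
non-negative projection of its aggregated term vector onto the fixed topic
basis) contracted with each word's topic profile; the 50 most important
keywords become graph nodes. Every utterance is assigned to exactly one
keyword node — the highest-ranked keyword it contains, or failing
containment the keyword whose embedding is closest in cosine. Edges carry
the average pairwise cosine similarity between the two nodes' sentence
embedding sets.

The multi-view form fits one topic model per speaker view and adds a cross
edge between a therapist node and a patient node whenever some
question-answer pair has its question utterance in the first node's sentence
set and the paired answer utterance in the second's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.decomposition import NMF
from sklearn.feature_extraction.text import TfidfVectorizer

from .io import QAPair, Speaker, Transcript, tokenize

__all__ = [
    "TopicModel", "KeywordNode", "KeywordGraph", "MultiViewKeywordGraph",
    "VectorizationError", "fit_topic_model", "score_keywords",
    "assign_sentences", "build_kcg", "build_kcg_mv", "topic_report",
]

log = logging.getLogger(__name__)

DEFAULT_N_TOPICS = 10
DEFAULT_TOP_K = 50


class VectorizationError(ValueError):
    """Vocabulary empty (or too small) after stop-word removal."""


@dataclass
class TopicModel:
    vocabulary: list[str]                  # ordered as vectorizer features
    topic_word: np.ndarray                 # (n_topics, vocab) nonnegative H
    n_topics: int
    vectorizer: TfidfVectorizer
    nmf: NMF
    doc_freq: np.ndarray                   # training document frequency per word

    def word_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabulary)}


@dataclass
class KeywordNode:
    keyword: str
    score: float
    sentence_set: set[int] = field(default_factory=set)  # utterance indices


@dataclass
class KeywordGraph:
    nodes: list[KeywordNode]               # rank order, <= 50
    edges: dict[tuple[int, int], float]    # node-list positions (i, j), i < j
    kcg_threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in self.edges.items():
            a[i, j] = w
            a[j, i] = w
        return a

    def to_networkx(self, speaker: str | None = None) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            attrs = {"score": float(node.score),
                     "n_sentences": len(node.sentence_set)}
            if speaker:
                attrs["speaker"] = speaker
            g.add_node(node.keyword, **attrs)
        for (i, j), w in sorted(self.edges.items()):
            g.add_edge(self.nodes[i].keyword, self.nodes[j].keyword,
                       weight=float(w), edge_type="intra")
        return g


@dataclass
class MultiViewKeywordGraph:
    therapist_kcg: KeywordGraph
    patient_kcg: KeywordGraph
    cross_edges: set[tuple[int, int]] = field(default_factory=set)
    # (therapist node position, patient node position)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for view, kcg in (("therapist", self.therapist_kcg),
                          ("patient", self.patient_kcg)):
            sub = kcg.to_networkx(speaker=view)
            g.add_nodes_from((f"{view}:{n}", d) for n, d in sub.nodes(data=True))
            g.add_edges_from((f"{view}:{u}", f"{view}:{v}",
                              {**d, "edge_type": f"intra_{view[0]}"})
                             for u, v, d in sub.edges(data=True))
        for (i, j) in sorted(self.cross_edges):
            g.add_edge(f"therapist:{self.therapist_kcg.nodes[i].keyword}",
                       f"patient:{self.patient_kcg.nodes[j].keyword}",
                       weight=1.0, edge_type="cross")
        return g


def fit_topic_model(
    sentences: list[str],
    n_topics: int = DEFAULT_N_TOPICS,
    seed: int = 0,
    min_df: int = 2,
    stop_words: str | list | None = "english",
) -> TopicModel:
    """Fit an NMF topic model over a sentence corpus (one sentence = one
    document), deterministic given the seed."""
    if n_topics < 2:
        raise ValueError("n_topics must be >= 2")
    vectorizer = TfidfVectorizer(stop_words=stop_words, min_df=min_df,
                                 token_pattern=r"[a-z0-9_']+", lowercase=True)
    try:
        x = vectorizer.fit_transform(sentences)
    except ValueError as exc:
        raise VectorizationError(str(exc)) from exc
    vocab = vectorizer.get_feature_names_out().tolist()
    if not vocab:
        raise VectorizationError("empty vocabulary after stop-word removal")
    if x.shape[0] < n_topics:
        raise ValueError(
            f"need >= {n_topics} sentences after vectorization, got {x.shape[0]}")
    nmf = NMF(n_components=n_topics, init="nndsvd", random_state=seed,
              max_iter=500, tol=1e-5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NMF convergence chatter on tiny corpora
        nmf.fit(x)
    doc_freq = np.asarray((x > 0).sum(axis=0)).ravel()
    return TopicModel(vocabulary=vocab, topic_word=nmf.components_.copy(),
                      n_topics=n_topics, vectorizer=vectorizer, nmf=nmf,
                      doc_freq=doc_freq)


def _transcript_term_vector(texts: list[str], model: TopicModel):
    return model.vectorizer.transform([" ".join(texts)])


def score_keywords(
    transcript: Transcript,
    model: TopicModel,
    k: int = DEFAULT_TOP_K,
    texts: list[str] | None = None,
) -> list[tuple[str, float]]:
    """Rank the transcript's in-vocabulary words by topic-weighted importance.

    importance(w) = loading . topic_word[:, w], where `loading` is the
    non-negative projection (NMF transform) of the transcript's aggregated
    term vector onto the fixed topic basis. Only words that occur in the
    transcript are eligible. Ties break by training document frequency, then
    lexicographically.
    """
    if texts is None:
        texts = transcript.texts()
    present = set()
    vocab_index = model.word_index()
    for text in texts:
        for tok in tokenize(text):
            idx = vocab_index.get(tok)
            if idx is not None:
                present.add(idx)
    if not present:
        log.warning("transcript %s shares no vocabulary with the topic model",
                    transcript.id)
        return []
    term_vec = _transcript_term_vector(texts, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loading = model.nmf.transform(term_vec)[0]           # (n_topics,)
    importance = loading @ model.topic_word                  # (vocab,)
    ranked = sorted(
        present,
        key=lambda i: (-importance[i], -model.doc_freq[i], model.vocabulary[i]),
    )
    return [(model.vocabulary[i], float(importance[i])) for i in ranked[:k]]


def assign_sentences(
    transcript: Transcript,
    keywords: list[tuple[str, float]],
    embeddings: np.ndarray,
    keyword_embedder=None,
    utterance_ids: list[int] | None = None,
) -> dict[str, set[int]]:
    """Assign each utterance to exactly one keyword node.

    Containment first: an utterance containing one or more of the keywords
    goes to the highest-ranked contained keyword. Otherwise it goes to the
    keyword whose embedding has maximal cosine with the utterance embedding
    (ties break by keyword rank). `keyword_embedder` maps a list of keyword
    strings to an embedding matrix; required only when some utterance
    contains no keyword.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    if utterance_ids is None:
        utterance_ids = [u.index for u in transcript.utterances]
        texts = transcript.texts()
    else:
        by_index = {u.index: u for u in transcript.utterances}
        texts = [by_index[i].text for i in utterance_ids]
    ranked_words = [w for w, _ in keywords]
    rank = {w: r for r, w in enumerate(ranked_words)}
    assignment: dict[str, set[int]] = {w: set() for w in ranked_words}
    kw_embs = None
    embeddings = np.asarray(embeddings, dtype=float)
    for utt_id, text, emb in zip(utterance_ids, texts, embeddings):
        tokens = set(tokenize(text))
        contained = [w for w in ranked_words if w in tokens]
        if contained:
            best = min(contained, key=lambda w: rank[w])
        else:
            if kw_embs is None:
                if keyword_embedder is None:
                    raise ValueError(
                        "keyword_embedder required: some utterance contains no keyword")
                kw_embs = np.asarray(keyword_embedder(ranked_words), dtype=float)
                norms = np.linalg.norm(kw_embs, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                kw_embs = kw_embs / norms
            e = emb / (np.linalg.norm(emb) or 1.0)
            cos = kw_embs @ e
            best = ranked_words[int(np.argmax(cos))]  # argmax takes first = best rank
        assignment[best].add(utt_id)
    return assignment


def _mean_pairwise_cosine(set_a: np.ndarray, set_b: np.ndarray) -> float:
    def unit(m):
        n = np.linalg.norm(m, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return m / n
    return float(np.mean(unit(set_a) @ unit(set_b).T))


def build_kcg(
    transcript: Transcript,
    model: TopicModel,
    embeddings: np.ndarray,
    k: int = DEFAULT_TOP_K,
    kcg_threshold: float = 0.0,
    keyword_embedder=None,
    utterance_ids: list[int] | None = None,
) -> KeywordGraph:
    """Build the keyword correlation graph of one transcript.

    Nodes are the top-k keywords with their assigned utterance sets (empty
    sets dropped); edge weight is the mean pairwise cosine between the two
    sentence-embedding sets, kept iff >= kcg_threshold.
    """
    keywords = score_keywords(transcript, model, k=k)
    if not keywords:
        return KeywordGraph(nodes=[], edges={}, kcg_threshold=kcg_threshold)
    assignment = assign_sentences(transcript, keywords, embeddings,
                                  keyword_embedder=keyword_embedder,
                                  utterance_ids=utterance_ids)
    if utterance_ids is None:
        utterance_ids = [u.index for u in transcript.utterances]
    pos_of = {utt: row for row, utt in enumerate(utterance_ids)}
    embeddings = np.asarray(embeddings, dtype=float)
    nodes = [KeywordNode(keyword=w, score=s, sentence_set=assignment[w])
             for w, s in keywords if assignment[w]]
    edges: dict[tuple[int, int], float] = {}
    sets = [embeddings[[pos_of[u] for u in sorted(node.sentence_set)]]
            for node in nodes]
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            w = _mean_pairwise_cosine(sets[i], sets[j])
            if w >= kcg_threshold:
                edges[(i, j)] = w
    return KeywordGraph(nodes=nodes, edges=edges, kcg_threshold=kcg_threshold)


def build_kcg_mv(
    transcript: Transcript,
    model_t: TopicModel,
    model_p: TopicModel,
    embeddings: np.ndarray,
    qapairs: list[QAPair],
    k: int = DEFAULT_TOP_K,
    kcg_threshold: float = 0.0,
    keyword_embedder=None,
) -> MultiViewKeywordGraph:
    """Multi-view KCG: per-view graphs from per-view topic models, plus
    presence-based question-answer cross edges."""
    t_ids = [u.index for u in transcript.utterances if u.speaker is Speaker.THERAPIST]
    p_ids = [u.index for u in transcript.utterances if u.speaker is Speaker.PATIENT]
    embeddings = np.asarray(embeddings, dtype=float)

    def view_kcg(ids, model):
        if not ids:
            return KeywordGraph(nodes=[], edges={}, kcg_threshold=kcg_threshold)
        return build_kcg(transcript, model, embeddings[ids], k=k,
                         kcg_threshold=kcg_threshold,
                         keyword_embedder=keyword_embedder, utterance_ids=ids)

    t_kcg = view_kcg(t_ids, model_t)
    p_kcg = view_kcg(p_ids, model_p)
    cross: set[tuple[int, int]] = set()
    if t_kcg.nodes and p_kcg.nodes:
        t_node_of = {u: i for i, node in enumerate(t_kcg.nodes)
                     for u in node.sentence_set}
        p_node_of = {u: j for j, node in enumerate(p_kcg.nodes)
                     for u in node.sentence_set}
        for pair in qapairs:
            for q in pair.question_turn.utterance_indices:
                i = t_node_of.get(q)
                if i is None:
                    continue
                for a in pair.answer_turn.utterance_indices:
                    j = p_node_of.get(a)
                    if j is not None:
                        cross.add((i, j))
    return MultiViewKeywordGraph(therapist_kcg=t_kcg, patient_kcg=p_kcg,
                                 cross_edges=cross)


def topic_report(model: TopicModel, top_n: int = 10) -> list[tuple[int, list[str]]]:
    """Top words per topic, the tabular counterpart of a topic-model figure."""
    report = []
    for t in range(model.n_topics):
        order = np.argsort(-model.topic_word[t])[:top_n]
        report.append((t, [model.vocabulary[i] for i in order]))
    return report
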