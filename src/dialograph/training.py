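"""Training and evaluation protocol.

Class-weighted binary cross entropy against the depressed/non-depressed
imbalance, Adam at 5e-4, per-epoch model selection on development-set
macro-F1, a fixed 0.5 decision threshold, and a multi-seed protocol
reporting mean +/- std of macro-F1, UAR (unweighted average recall),
accuracy and macro precision on both development and test splits. The
similarity threshold is treated as a hyper-parameter and chosen by the best
mean development macro-F1 over a grid.

All corpus-level statistics (topic models, vectorizer vocabularies) are
fitted on the training split only; development and test transcripts never
influence graph construction.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from ._autodiff import Adam, Tensor
from .embeddings import EncoderSpec, make_encoder
from .io import Speaker, Transcript, pair_questions_answers, segment_turns
from .kcg import TopicModel, build_kcg, build_kcg_mv, fit_topic_model
from .nn import (GraphClassifier, GraphData, ModelConfig, build_classifier,
                 normalized_adjacency)
from .similarity import build_mv_similarity_graph, build_similarity_graph

__all__ = [
    "TrainConfig", "EvalReport", "class_weights", "weighted_bce",
    "compute_metrics", "majority_baseline_metrics",
    "prepare_datasets", "dataset_fingerprint",
    "train_model", "evaluate", "run_protocol",
]

METRIC_NAMES = ("macro_f1", "uar", "accuracy", "macro_precision")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    max_epochs: int = 100
    batch_size: int = 8
    seeds: tuple = (0, 1, 2, 3, 4)
    similarity_threshold_grid: tuple = (0.3, 0.4, 0.5, 0.6, 0.7)
    kcg_threshold: float = 0.0
    early_stop_patience: int = 20
    decision_threshold: float = 0.5
    n_topics: int = 10
    top_k_keywords: int = 50

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not self.seeds:
            raise ValueError("need at least one seed")


# ---------------------------------------------------------------------------
# loss and metrics

def class_weights(labels) -> dict[int, float]:
    """Per-class loss weights w_c = N / (2 N_c), equalising the weighted
    class masses."""
    labels = [int(y) for y in labels]
    n = len(labels)
    n_pos = sum(labels)
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the training labels")
    return {0: n / (2.0 * n_neg), 1: n / (2.0 * n_pos)}


def weighted_bce(prob, label: int, weights: dict[int, float],
                 eps: float = 1e-7):
    """Class-weighted binary cross entropy for one prediction.

    Accepts either a float probability (returns float) or an autodiff
    Tensor (returns a scalar Tensor on the graph). The probability is
    clamped to (eps, 1 - eps) before the logarithm.
    """
    label = int(label)
    w = weights[label]
    if isinstance(prob, Tensor):
        p = prob.clip(eps, 1.0 - eps)
        if label == 1:
            return (p.log() * (-w)).sum()
        return ((1.0 - p).log() * (-w)).sum()
    p = min(max(float(prob), eps), 1.0 - eps)
    return -w * (label * math.log(p) + (1 - label) * math.log(1.0 - p))


def compute_metrics(y_true, y_pred) -> dict[str, float]:
    """Macro-F1, UAR, accuracy and macro precision over binary labels.

    A class absent from y_true contributes 0 to its per-class terms.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and equal length")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0)
    return {
        "macro_f1": float(f1.mean()),
        "uar": float(rec.mean()),
        "accuracy": float((y_true == y_pred).mean()),
        "macro_precision": float(prec.mean()),
    }


def majority_baseline_metrics(train_labels, y_true) -> dict[str, float]:
    """Metrics of the constant classifier predicting the training majority."""
    majority = int(np.mean([int(y) for y in train_labels]) >= 0.5)
    return compute_metrics(y_true, [majority] * len(y_true))


# ---------------------------------------------------------------------------
# corpus -> GraphData pipeline

def _similarity_graphdata(transcript: Transcript, emb: np.ndarray,
                          threshold: float, multiview: bool) -> GraphData:
    if not multiview:
        g = build_similarity_graph(emb, threshold)
        return GraphData(ahat=normalized_adjacency(g.adjacency()),
                         n_t=g.n_nodes, n_p=0, label=transcript.label or 0,
                         x=emb, multiview=False, id=transcript.id)
    qapairs = pair_questions_answers(segment_turns(transcript))
    mv = build_mv_similarity_graph(transcript, emb, qapairs, threshold)
    t_ids = mv.therapist_graph.node_ids
    p_ids = mv.patient_graph.node_ids
    n_t, n_p = len(t_ids), len(p_ids)
    pos = {utt: k for k, utt in enumerate(t_ids)}
    pos.update({utt: n_t + k for k, utt in enumerate(p_ids)})
    a = np.zeros((n_t + n_p, n_t + n_p))
    for (i, j), w in mv.therapist_graph.edges.items():
        a[pos[i], pos[j]] = a[pos[j], pos[i]] = w
    for (i, j), w in mv.patient_graph.edges.items():
        a[pos[i], pos[j]] = a[pos[j], pos[i]] = w
    for (q, ans) in mv.cross_edges:
        a[pos[q], pos[ans]] = a[pos[ans], pos[q]] = 1.0
    x = emb[t_ids + p_ids] if (t_ids or p_ids) else np.zeros((0, emb.shape[1]))
    return GraphData(ahat=normalized_adjacency(a), n_t=n_t, n_p=n_p,
                     label=transcript.label or 0, x=x, multiview=True,
                     id=transcript.id)


def _kcg_graphdata(transcript: Transcript, emb: np.ndarray,
                   models: dict, encoder, k: int, kcg_threshold: float,
                   multiview: bool) -> GraphData:
    if not multiview:
        kcg = build_kcg(transcript, models["global"], emb, k=k,
                        kcg_threshold=kcg_threshold, keyword_embedder=encoder)
        utt_row = {u.index: r for r, u in enumerate(transcript.utterances)}
        sets = [emb[[utt_row[u] for u in sorted(node.sentence_set)]]
                for node in kcg.nodes]
        return GraphData(ahat=normalized_adjacency(kcg.adjacency()),
                         n_t=kcg.n_nodes, n_p=0, label=transcript.label or 0,
                         sentence_sets=sets, multiview=False, id=transcript.id)
    qapairs = pair_questions_answers(segment_turns(transcript))
    mv = build_kcg_mv(transcript, models["therapist"], models["patient"], emb,
                      qapairs, k=k, kcg_threshold=kcg_threshold,
                      keyword_embedder=encoder)
    t_ids = [u.index for u in transcript.utterances if u.speaker is Speaker.THERAPIST]
    p_ids = [u.index for u in transcript.utterances if u.speaker is Speaker.PATIENT]
    t_row = {utt: r for r, utt in enumerate(t_ids)}
    p_row = {utt: r for r, utt in enumerate(p_ids)}
    emb_t, emb_p = emb[t_ids], emb[p_ids]
    n_t, n_p = mv.therapist_kcg.n_nodes, mv.patient_kcg.n_nodes
    a = np.zeros((n_t + n_p, n_t + n_p))
    for (i, j), w in mv.therapist_kcg.edges.items():
        a[i, j] = a[j, i] = w
    for (i, j), w in mv.patient_kcg.edges.items():
        a[n_t + i, n_t + j] = a[n_t + j, n_t + i] = w
    for (i, j) in mv.cross_edges:
        a[i, n_t + j] = a[n_t + j, i] = 1.0
    sets = [emb_t[[t_row[u] for u in sorted(node.sentence_set)]]
            for node in mv.therapist_kcg.nodes]
    sets += [emb_p[[p_row[u] for u in sorted(node.sentence_set)]]
             for node in mv.patient_kcg.nodes]
    return GraphData(ahat=normalized_adjacency(a), n_t=n_t, n_p=n_p,
                     label=transcript.label or 0, sentence_sets=sets,
                     multiview=True, id=transcript.id)


def fit_corpus_topic_models(train_transcripts: list[Transcript],
                            variant: str, n_topics: int,
                            seed: int = 0) -> dict[str, TopicModel]:
    """Fit the topic models a KCG variant needs, on training sentences only."""
    models: dict[str, TopicModel] = {}
    if variant == "kcg_baseline":
        sentences = [u.text for t in train_transcripts for u in t.utterances]
        models["global"] = fit_topic_model(sentences, n_topics=n_topics, seed=seed)
    elif variant == "kcg_mv":
        t_sents = [u.text for t in train_transcripts for u in t.utterances
                   if u.speaker is Speaker.THERAPIST]
        p_sents = [u.text for t in train_transcripts for u in t.utterances
                   if u.speaker is Speaker.PATIENT]
        models["therapist"] = fit_topic_model(t_sents, n_topics=n_topics, seed=seed)
        models["patient"] = fit_topic_model(p_sents, n_topics=n_topics, seed=seed)
    return models


def prepare_datasets(
    transcripts_by_split: dict[str, list[Transcript]],
    variant: str,
    encoder: Optional[Callable] = None,
    encoder_spec: Optional[EncoderSpec] = None,
    similarity_threshold: float = 0.5,
    kcg_threshold: float = 0.0,
    n_topics: int = 10,
    top_k_keywords: int = 50,
    topic_seed: int = 0,
) -> dict[str, list[GraphData]]:
    """Turn split transcripts into per-split lists of preprocessed graphs.

    Topic models (KCG variants) are fitted on the ``train`` split only;
    every per-transcript graph is then a function of that transcript and
    those fixed models.
    """
    if encoder is None:
        encoder = make_encoder(encoder_spec or EncoderSpec(dim=64))
    models = fit_corpus_topic_models(transcripts_by_split["train"], variant,
                                     n_topics, seed=topic_seed)
    out: dict[str, list[GraphData]] = {}
    for split, transcripts in transcripts_by_split.items():
        graphs = []
        for t in transcripts:
            emb = encoder(t.texts())
            if variant in ("similarity_baseline", "similarity_mv"):
                g = _similarity_graphdata(t, emb, similarity_threshold,
                                          variant == "similarity_mv")
            else:
                g = _kcg_graphdata(t, emb, models, encoder, top_k_keywords,
                                   kcg_threshold, variant == "kcg_mv")
            if g.n_nodes > 0:
                graphs.append(g)
        out[split] = graphs
    return out


def dataset_fingerprint(datasets: dict[str, list[GraphData]],
                        splits: Optional[list[str]] = None) -> str:
    """SHA-256 over the byte content of the chosen splits' graphs; used to
    verify that graph construction ignores held-out data."""
    h = hashlib.sha256()
    for split in splits or sorted(datasets):
        for g in datasets[split]:
            h.update(g.id.encode())
            h.update(np.int64(g.label).tobytes())
            h.update(np.ascontiguousarray(g.ahat).tobytes())
            if g.x is not None:
                h.update(np.ascontiguousarray(g.x).tobytes())
            if g.sentence_sets is not None:
                for s in g.sentence_sets:
                    h.update(np.ascontiguousarray(s).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# training

def _predict(model: GraphClassifier, dataset: list[GraphData],
             decision_threshold: float = 0.5):
    probs = np.array([model(g).item() for g in dataset])
    preds = (probs >= decision_threshold).astype(int)
    labels = np.array([g.label for g in dataset], dtype=int)
    return probs, preds, labels


def evaluate(model: GraphClassifier, dataset: list[GraphData],
             decision_threshold: float = 0.5) -> dict[str, float]:
    model.eval()
    _, preds, labels = _predict(model, dataset, decision_threshold)
    return compute_metrics(labels, preds)


def train_model(
    datasets: dict[str, list[GraphData]],
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[GraphClassifier, list[dict]]:
    """Train one classifier; restore the epoch with the best dev macro-F1.

    Returns the trained model and a per-epoch history of train loss and dev
    metrics. Fully deterministic given the seed.
    """
    train_set = datasets["train"]
    dev_set = datasets["dev"]
    feat_dim = (train_set[0].x.shape[1] if train_set[0].x is not None
                else train_set[0].sentence_sets[0].shape[1])
    model = build_classifier(model_config, feat_dim, seed=seed)
    model.reseed_dropout(seed + 1)
    weights = class_weights([g.label for g in train_set])
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    best = {"macro_f1": -1.0}
    best_state = model.state()
    best_epoch = -1
    since_best = 0
    for epoch in range(train_config.max_epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for start in range(0, len(order), train_config.batch_size):
            batch = [train_set[i] for i in order[start:start + train_config.batch_size]]
            opt.zero_grad()
            loss = None
            for g in batch:
                term = weighted_bce(model(g), g.label, weights)
                loss = term if loss is None else loss + term
            loss = loss * (1.0 / len(batch))
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}")
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
        dev_metrics = evaluate(model, dev_set, train_config.decision_threshold)
        history.append({"epoch": epoch,
                        "train_loss": epoch_loss / len(train_set),
                        **{f"dev_{k}": v for k, v in dev_metrics.items()}})
        if dev_metrics["macro_f1"] > best["macro_f1"]:
            best = dev_metrics
            best_state = model.state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_config.early_stop_patience:
                break
    model.load_state(best_state)
    model.eval()
    for row in history:
        row["best_epoch"] = best_epoch
    return model, history


# ---------------------------------------------------------------------------
# multi-seed protocol

@dataclass
class EvalReport:
    """Per-seed and aggregated dev/test metrics of one protocol run."""
    variant: str
    chosen_threshold: Optional[float]
    rows: list[dict] = field(default_factory=list)
    # each row: {"seed", "threshold", "dev_<metric>", "test_<metric>"}

    def aggregate(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for split in ("dev", "test"):
            for m in METRIC_NAMES:
                vals = [r[f"{split}_{m}"] for r in self.rows]
                out[f"{split}_{m}"] = {"mean": float(np.mean(vals)),
                                       "std": float(np.std(vals))}
        return out

    def to_dict(self) -> dict:
        return {"variant": self.variant,
                "chosen_threshold": self.chosen_threshold,
                "rows": self.rows,
                "aggregate": self.aggregate()}

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows)

    def summary_lines(self) -> list[str]:
        agg = self.aggregate()
        lines = [f"variant: {self.variant}  "
                 f"threshold: {self.chosen_threshold}"]
        for split in ("dev", "test"):
            parts = [f"{m}={agg[f'{split}_{m}']['mean']:.3f}"
                     f"±{agg[f'{split}_{m}']['std']:.3f}" for m in METRIC_NAMES]
            lines.append(f"  {split}: " + "  ".join(parts))
        return lines


def run_protocol(
    transcripts_by_split: dict[str, list[Transcript]],
    variant: str,
    train_config: TrainConfig = TrainConfig(),
    model_config: Optional[ModelConfig] = None,
    encoder: Optional[Callable] = None,
    encoder_spec: Optional[EncoderSpec] = None,
) -> EvalReport:
    """Multi-seed protocol: for each similarity threshold on the grid, train
    once per seed; pick the threshold with the best mean dev macro-F1; report
    per-seed and mean +/- std metrics at that threshold.

    KCG variants have no tuned threshold (a single fixed value is used).
    """
    model_config = model_config or ModelConfig(variant=variant)
    if model_config.variant != variant:
        raise ValueError("model_config.variant must match variant")
    if variant in ("similarity_baseline", "similarity_mv"):
        grid = list(train_config.similarity_threshold_grid)
    else:
        grid = [train_config.kcg_threshold]
    results: dict[float, list[dict]] = {}
    for threshold in grid:
        datasets = prepare_datasets(
            transcripts_by_split, variant, encoder=encoder,
            encoder_spec=encoder_spec,
            similarity_threshold=threshold,
            kcg_threshold=train_config.kcg_threshold,
            n_topics=train_config.n_topics,
            top_k_keywords=train_config.top_k_keywords)
        rows = []
        for seed in train_config.seeds:
            model, _ = train_model(datasets, model_config, train_config, seed=seed)
            dev = evaluate(model, datasets["dev"], train_config.decision_threshold)
            test = evaluate(model, datasets["test"], train_config.decision_threshold)
            rows.append({"seed": int(seed), "threshold": float(threshold),
                         **{f"dev_{k}": v for k, v in dev.items()},
                         **{f"test_{k}": v for k, v in test.items()}})
        results[threshold] = rows
    chosen = max(grid, key=lambda th: float(
        np.mean([r["dev_macro_f1"] for r in results[th]])))
    return EvalReport(variant=variant, chosen_threshold=float(chosen),
                      rows=results[chosen])
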