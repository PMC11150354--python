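"""Graph neural architectures for the four graph variants.

Each classifier is: GCN message passing over the (weighted, self-looped,
symmetrically degree-normalised) adjacency, a multi-head-attention readout,
and a logistic classification head. Multi-view variants run the GCN over
the joint graph (both views plus cross edges), then encode each view with
self-attention, exchange information with cross-attention in both
directions, and fuse the two attended view summaries by element-wise mean
("inter-view attention, mean combination"). KCG variants first pool each
keyword node's sentence-embedding set into a node feature with a
multi-head-attention *node encoder*.

Everything runs on the package's own numpy autodiff engine; weights are
float64 and initialisation is a pure function of the model seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._autodiff import Tensor, stack

__all__ = [
    "ModelConfig", "GraphData", "normalized_adjacency",
    "Linear", "MultiHeadAttention", "GCNLayer", "NodeEncoder",
    "AttentionReadout", "InterViewAttentionMean", "ClassifierHead",
    "GraphClassifier", "build_classifier",
    "gcn_forward", "attention_readout", "node_encoder", "mv_inter_att_mean",
    "classify",
]

VARIANTS = ("similarity_baseline", "similarity_mv", "kcg_baseline", "kcg_mv")


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "similarity_mv"
    hidden_dim: int = 128
    n_gcn_layers: int = 2
    n_attention_heads: int = 4
    dropout: float = 0.2
    readout: str = "attention_pool"  # or "mean_pool"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.hidden_dim % self.n_attention_heads:
            raise ValueError("hidden_dim must be divisible by n_attention_heads")
        if self.n_gcn_layers < 1:
            raise ValueError("need at least one GCN layer")


@dataclass
class GraphData:
    """One transcript, preprocessed into arrays a classifier consumes.

    Multi-view graphs are laid out as a single block adjacency: therapist
    nodes first (``n_t`` of them), then patient nodes, with cross edges in
    the off-diagonal blocks. For KCG variants ``sentence_sets`` holds each
    node's sentence-embedding set in the same node order and ``x`` is None.
    """
    ahat: np.ndarray                              # (n, n) normalised adjacency
    n_t: int
    n_p: int
    label: int = 0
    x: Optional[np.ndarray] = None                # (n, feat_dim)
    sentence_sets: Optional[list] = None          # list of (m_i, feat_dim)
    multiview: bool = False
    id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.ahat.shape[0]


def normalized_adjacency(adj: np.ndarray) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} with degrees floored away from zero."""
    n = adj.shape[0]
    if n == 0:
        return adj.copy()
    a = adj + np.eye(n)
    deg = a.sum(axis=1)
    deg = np.maximum(deg, 1e-8)
    d = 1.0 / np.sqrt(deg)
    return a * d[:, None] * d[None, :]


# ---------------------------------------------------------------------------
# layers

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros((1, d_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class MultiHeadAttention(Module):
    """Single-block scaled dot-product attention with h heads.

    ``__call__(q, k, v)`` accepts (n, d) inputs; self-attention passes the
    same tensor three times, cross-attention mixes the two views.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, n: int) -> Tensor:
        # (n, d) -> (h, n, d_head)
        return x.reshape(n, self.n_heads, self.d_head).transpose(1, 0, 2)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        n_q, n_k = q.shape[0], k.shape[0]
        qh = self._split(self.wq(q), n_q)
        kh = self._split(self.wk(k), n_k)
        vh = self._split(self.wv(v), n_k)
        scores = (qh @ kh.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        out = attn @ vh                                     # (h, n_q, d_head)
        out = out.transpose(1, 0, 2).reshape(n_q, self.dim)
        return self.wo(out)


class GCNLayer(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.lin = Linear(d_in, d_out, rng)

    def __call__(self, ahat: np.ndarray, x: Tensor) -> Tensor:
        return self.lin(Tensor(ahat) @ x)


class NodeEncoder(Module):
    """Pool a keyword node's sentence-embedding set into one vector:
    multi-head self-attention over the set, then mean pooling."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, n_heads, rng)

    def __call__(self, sentence_set: np.ndarray) -> Tensor:
        if sentence_set.shape[0] == 0:
            raise ValueError("node encoder requires a non-empty sentence set")
        x = Tensor(np.asarray(sentence_set, dtype=float))
        return self.attn(x, x, x).mean(axis=0, keepdims=True)  # (1, dim)


class AttentionReadout(Module):
    """Graph-level readout: self-attention over node features, mean-pooled."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.attn = MultiHeadAttention(dim, n_heads, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.attn(x, x, x).mean(axis=0, keepdims=True)  # (1, dim)


class InterViewAttentionMean(Module):
    """Multi-view fusion: per-view self-attention encodings, cross-attention
    in both directions, element-wise mean of the two attended summaries."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.enc_t = MultiHeadAttention(dim, n_heads, rng)
        self.enc_p = MultiHeadAttention(dim, n_heads, rng)
        self.cross_t = MultiHeadAttention(dim, n_heads, rng)  # therapist queries
        self.cross_p = MultiHeadAttention(dim, n_heads, rng)  # patient queries
        self.dim = dim

    def __call__(self, xt: Optional[Tensor], xp: Optional[Tensor]) -> Tensor:
        zero = Tensor(np.zeros((1, self.dim)))
        ht = self.enc_t(xt, xt, xt) if xt is not None else zero
        hp = self.enc_p(xp, xp, xp) if xp is not None else zero
        st = self.cross_t(ht, hp, hp).mean(axis=0, keepdims=True)
        sp = self.cross_p(hp, ht, ht).mean(axis=0, keepdims=True)
        return (st + sp) * 0.5


class ClassifierHead(Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        self.lin = Linear(dim, 1, rng)

    def __call__(self, g: Tensor) -> Tensor:
        return self.lin(g).sigmoid()  # (1, 1) probability of the depressed class


# ---------------------------------------------------------------------------
# full classifiers

class GraphClassifier(Module):
    """One of the four graph-variant depression classifiers."""

    def __init__(self, config: ModelConfig, feat_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.feat_dim = feat_dim
        h = config.hidden_dim
        heads = config.n_attention_heads
        if config.variant in ("kcg_baseline", "kcg_mv"):
            if feat_dim % heads:
                raise ValueError("embedding dim must be divisible by n_heads "
                                 "for the node encoder")
            self.node_enc_t = NodeEncoder(feat_dim, heads, rng)
            self.node_enc_p = (NodeEncoder(feat_dim, heads, rng)
                               if config.variant == "kcg_mv" else None)
        else:
            self.node_enc_t = None
            self.node_enc_p = None
        self.proj = Linear(feat_dim, h, rng)
        self.gcn_layers = [GCNLayer(h, h, rng) for _ in range(config.n_gcn_layers)]
        if config.variant.endswith("_mv"):
            self.fusion = InterViewAttentionMean(h, heads, rng)
            self.readout = None
        else:
            self.fusion = None
            self.readout = (AttentionReadout(h, heads, rng)
                            if config.readout == "attention_pool" else None)
        self.head = ClassifierHead(h, rng)
        self.training = False
        self._drop_rng = np.random.default_rng(seed + 1)

    # -- mode ------------------------------------------------------------
    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    def reseed_dropout(self, seed: int):
        self._drop_rng = np.random.default_rng(seed)

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0:
            return x
        mask = (self._drop_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    # -- forward ---------------------------------------------------------
    def _node_features(self, data: GraphData) -> Tensor:
        if data.sentence_sets is not None:
            encoded = []
            for pos, sset in enumerate(data.sentence_sets):
                enc = (self.node_enc_p if (self.node_enc_p is not None
                                           and pos >= data.n_t)
                       else self.node_enc_t)
                encoded.append(enc(sset).reshape(sset.shape[1]))
            return stack(encoded, axis=0)
        return Tensor(np.asarray(data.x, dtype=float))

    def forward(self, data: GraphData) -> Tensor:
        if data.n_nodes == 0:
            raise ValueError("cannot classify an empty graph")
        x = self._node_features(data)
        x = self.proj(x)
        for layer in self.gcn_layers:
            x = self._dropout(layer(data.ahat, x).relu())
        if self.fusion is not None:
            xt = x[0:data.n_t] if data.n_t else None
            xp = x[data.n_t:data.n_t + data.n_p] if data.n_p else None
            g = self.fusion(xt, xp)
        elif self.readout is not None:
            g = self.readout(x)
        else:
            g = x.mean(axis=0, keepdims=True)
        return self.head(self._dropout(g))

    __call__ = forward

    # -- persistence ------------------------------------------------------
    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match parameter count")
        for p, s in zip(params, state):
            p.data = s.copy()


def build_classifier(config: ModelConfig, feat_dim: int, seed: int = 0) -> GraphClassifier:
    return GraphClassifier(config, feat_dim, seed=seed)


# ---------------------------------------------------------------------------
# functional forms (thin wrappers used directly in tests and small scripts)

def gcn_forward(adj: np.ndarray, x: np.ndarray, weights: list[np.ndarray],
                biases: Optional[list[np.ndarray]] = None) -> np.ndarray:
    """Plain-numpy GCN stack: relu(D^{-1/2}(A+I)D^{-1/2} X W + b) per layer."""
    ahat = normalized_adjacency(np.asarray(adj, dtype=float))
    h = np.asarray(x, dtype=float)
    for i, w in enumerate(weights):
        h = ahat @ h @ w
        if biases is not None:
            h = h + biases[i]
        h = np.maximum(h, 0.0)
    return h


def node_encoder(sentence_set: np.ndarray, dim: int, n_heads: int,
                 seed: int = 0) -> np.ndarray:
    enc = NodeEncoder(dim, n_heads, np.random.default_rng(seed))
    return enc(np.asarray(sentence_set, dtype=float)).data


def attention_readout(node_features: np.ndarray, n_heads: int = 4,
                      seed: int = 0) -> np.ndarray:
    x = np.asarray(node_features, dtype=float)
    ro = AttentionReadout(x.shape[1], n_heads, np.random.default_rng(seed))
    return ro(Tensor(x)).data


def mv_inter_att_mean(view_t: Optional[np.ndarray], view_p: Optional[np.ndarray],
                      n_heads: int = 4, seed: int = 0) -> np.ndarray:
    dim = (view_t if view_t is not None else view_p).shape[1]
    fusion = InterViewAttentionMean(dim, n_heads, np.random.default_rng(seed))
    xt = Tensor(np.asarray(view_t, dtype=float)) if view_t is not None else None
    xp = Tensor(np.asarray(view_p, dtype=float)) if view_p is not None else None
    return fusion(xt, xp).data


def classify(embedding: np.ndarray, w: np.ndarray, b: float) -> float:
    """Logistic head on a graph embedding: sigmoid(embedding . w + b)."""
    z = float(np.asarray(embedding).ravel() @ np.asarray(w).ravel() + b)
    return 1.0 / (1.0 + np.exp(-z))
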