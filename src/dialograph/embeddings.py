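"""Sentence encoders with a pluggable backend.

Two backends share one interface: a production transformer encoder
(``sentence-transformers`` all-mpnet-base-v2, 768-d) and a deterministic
hash-token encoder that needs no model download and is a pure function of
(text, dim, seed). The deterministic encoder sums a seeded unit vector per
token and L2-normalises, so texts sharing more tokens have higher cosine
similarity in expectation — enough structure for every downstream graph
builder to be exercised meaningfully.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .io import tokenize

__all__ = [
    "EncoderSpec", "EncoderBackendError", "ZeroTokenError",
    "deterministic_embed", "encode_sentences", "make_encoder",
]

DEFAULT_PRODUCTION_MODEL = "all-mpnet-base-v2"
DEFAULT_DIM = 768


class EncoderBackendError(RuntimeError):
    """The requested encoder backend cannot be loaded."""


class ZeroTokenError(ValueError):
    """Text yields no tokens and therefore no embedding."""


@dataclass(frozen=True)
class EncoderSpec:
    backend: str = "deterministic_test"  # or "transformer"
    model_name: str = DEFAULT_PRODUCTION_MODEL
    dim: int = DEFAULT_DIM
    normalize: bool = True
    seed: int = 0


def _token_vector(token: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(f"{seed}:{token}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)

_token_cache: dict[tuple[str, int, int], np.ndarray] = {}


def deterministic_embed(text: str, dim: int = DEFAULT_DIM, seed: int = 0) -> np.ndarray:
    """Hash-token sentence embedding: L2-normalised sum of per-token unit
    vectors, each derived from a seeded hash of the token."""
    if dim <= 0:
        raise ValueError("dim must be positive")
    tokens = tokenize(text)
    if not tokens:
        raise ZeroTokenError(f"text {text!r} has no tokens")
    acc = np.zeros(dim)
    for tok in tokens:
        key = (tok, dim, seed)
        vec = _token_cache.get(key)
        if vec is None:
            vec = _token_vector(tok, dim, seed)
            if len(_token_cache) < 200_000:
                _token_cache[key] = vec
        acc += vec
    norm = np.linalg.norm(acc)
    if norm == 0:  # pathological token cancellation
        acc[0] = 1.0
        norm = 1.0
    return acc / norm


def _load_transformer(model_name: str):
    try:
        from sentence_transformers import SentenceTransformer
    except ImportError as exc:
        raise EncoderBackendError(
            "the 'transformer' backend needs the sentence-transformers package "
            "and a downloaded model; use backend='deterministic_test' for "
            "offline/deterministic runs"
        ) from exc
    return SentenceTransformer(model_name)


def encode_sentences(texts: list[str], spec: EncoderSpec = EncoderSpec()) -> np.ndarray:
    """Encode a list of sentences into an (n, dim) float array, order kept."""
    if spec.backend == "deterministic_test":
        mat = np.stack([deterministic_embed(t, spec.dim, spec.seed) for t in texts])
    elif spec.backend == "transformer":
        model = _load_transformer(spec.model_name)
        mat = np.asarray(model.encode(list(texts)), dtype=float)
    else:
        raise ValueError(f"unknown encoder backend {spec.backend!r}")
    if spec.normalize:
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        mat = mat / norms
    return mat


def make_encoder(spec: EncoderSpec = EncoderSpec()):
    """Return a closure mapping a list of texts to an embedding matrix."""
    def encoder(texts: list[str]) -> np.ndarray:
        return encode_sentences(list(texts), spec)
    return encoder
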