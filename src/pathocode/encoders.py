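"""Numeric kernels and text encoders.

The kernels (scaled dot-product attention, softmax, masked cross-entropy,
cosine similarity) are the small verifiable pieces of the transformer
arithmetic the pipeline relies on.  The shipped reference encoder is a
seeded character-n-gram feature-hashing encoder: deterministic, dependency
free, and robust to single-character corruptions, which makes it a usable
stand-in for a contextual sentence encoder at desk scale.  An adapter
contract for external transformer encoders is provided for users who have
such a model available.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .corpus_io import IGNORE_INDEX


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: exp(z - max) normalized along *axis*."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite inputs")
    shifted = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_k)) V.

    Each output row is a convex combination of the rows of V.
    """
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise ValueError("Q, K, V must be 2-D matrices")
    d_k = Q.shape[1]
    if d_k == 0:
        raise ValueError("key dimensionality d_k must be positive")
    if K.shape[1] != d_k:
        raise ValueError("Q and K must share column count d_k")
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must share row count")
    scores = Q @ K.T / np.sqrt(d_k)
    return softmax(scores, axis=-1) @ V


def cross_entropy(
    y_true: np.ndarray, y_hat: np.ndarray, ignore_index: int = IGNORE_INDEX
) -> float:
    """Mean -ln p(true class) over positions whose label != ignore_index.

    ``y_true`` holds integer class indices (or ignore_index); ``y_hat`` holds
    probability rows summing to 1.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_hat.ndim == 1:
        y_hat = y_hat[None, :]
        y_true = np.atleast_1d(y_true)
    keep = y_true != ignore_index
    if not np.any(keep):
        raise ValueError("no unmasked positions")
    probs = y_hat[keep, y_true[keep]]
    return float(np.mean(-np.log(np.clip(probs, 1e-300, None))))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# Encoder contract and the hashing reference encoder
# ---------------------------------------------------------------------------

class Encoder(Protocol):
    """Any deterministic text encoder: texts -> (n, dim) float matrix."""

    dim: int

    def encode(self, texts: Sequence[str]) -> np.ndarray: ...

    def fingerprint(self) -> str: ...


@dataclass
class HashingEncoder:
    """Character-n-gram feature-hashing encoder with signed buckets.

    Words are lowercased and padded with ``#`` boundary marks; every n-gram
    for n in ``ngram_range`` is hashed (keyed blake2b, so results are stable
    across processes and platforms) into one of ``dim`` signed buckets.
    Rows are L2-normalized.  A text with no features maps to the first unit
    basis vector so downstream cosine arithmetic stays defined.
    """

    dim: int = 256
    seed: int = 0
    ngram_range: tuple[int, int] = (3, 5)
    unit_norm: bool = True
    _cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.dim < 16:
            raise ValueError("dim must be at least 16")
        self._key = str(self.seed).encode()

    def _hash(self, gram: str) -> int:
        digest = hashlib.blake2b(gram.encode("utf-8"), key=self._key, digest_size=8)
        return int.from_bytes(digest.digest(), "little")

    def _encode_one(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=np.float64)
        lo, hi = self.ngram_range
        n_feats = 0
        for word in text.lower().split():
            padded = f"#{word}#"
            for n in range(lo, hi + 1):
                if len(padded) < n:
                    continue
                for i in range(len(padded) - n + 1):
                    h = self._hash(padded[i : i + n])
                    sign = 1.0 if (h >> 63) & 1 else -1.0
                    vec[h % self.dim] += sign
                    n_feats += 1
        if n_feats == 0:
            vec[0] = 1.0
            return vec
        if self.unit_norm:
            vec /= np.linalg.norm(vec)
        return vec

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        out = np.empty((len(texts), self.dim), dtype=np.float64)
        for i, text in enumerate(texts):
            cached = self._cache.get(text)
            if cached is None:
                cached = self._encode_one(text)
                self._cache[text] = cached
            out[i] = cached
        return out

    def fingerprint(self) -> str:
        return f"hashing:dim={self.dim}:seed={self.seed}:ngram={self.ngram_range}"


class ExternalEncoderAdapter:
    """Adapter for a transformer sentence encoder (mean pooling, unit norm).

    Requires the optional ``transformers`` and ``torch`` dependencies; it is
    configuration-compatible with :class:`HashingEncoder` so indexes built
    with either satisfy the same contract.
    """

    def __init__(self, model_id: str, dim: int | None = None):
        try:
            from transformers import AutoModel, AutoTokenizer  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "ExternalEncoderAdapter requires the 'transformers' package"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_id)
        self._model = AutoModel.from_pretrained(model_id)
        self.model_id = model_id
        self.dim = dim or self._model.config.hidden_size

    def encode(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        import torch

        with torch.no_grad():
            batch = self._tokenizer(list(texts), padding=True, return_tensors="pt")
            states = self._model(**batch).last_hidden_state
            mask = batch["attention_mask"].unsqueeze(-1).float()
            pooled = (states * mask).sum(1) / mask.sum(1)
            pooled = torch.nn.functional.normalize(pooled, dim=-1)
        return pooled.numpy().astype(np.float64)

    def fingerprint(self) -> str:  # pragma: no cover
        return f"external:{self.model_id}"


def make_encoder(config: dict) -> Encoder:
    """Build an encoder from a config mapping ``{type, dim, seed, model_id?}``."""
    etype = config.get("type", "hashing")
    if etype == "hashing":
        return HashingEncoder(
            dim=int(config.get("dim", 256)), seed=int(config.get("seed", 0))
        )
    if etype == "external":
        return ExternalEncoderAdapter(config["model_id"], config.get("dim"))
    raise ValueError(f"unknown encoder type {etype!r}")
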