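"""Reference token-level entity tagger.

The shipped tagger is a windowed softmax classifier: each token is
represented by the concatenated hashed embeddings of itself and its
±window neighbors, and a multinomial softmax layer maps that to the seven
BIO labels.  This keeps the train/evaluate protocol (80/20 report split,
short AdamW training, masked cross-entropy, token-level metrics) fully
runnable on one CPU; the :class:`TokenClassifier` contract lets a
transformer-based tagger plug in unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from . import corpus_io
from .corpus_io import (
    BIO_LABELS,
    LABEL_TO_ID,
    ID_TO_LABEL,
    Report,
    TaggedSequence,
    EntityMention,
)
from .encoders import HashingEncoder
from .linear import SoftmaxRegression, TrainConfig


class TokenClassifier(Protocol):
    """Contract for pluggable token taggers over feature rows."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TokenClassifier": ...

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class NERConfig:
    """Training configuration for the reference tagger.

    Defaults follow a short fine-tuning recipe: 3 epochs, batch size 8,
    weight decay 0.01, with the learning rate scaled to the linear
    reference model.  ``window`` is the context half-width in tokens.
    """

    epochs: int = 3
    learning_rate: float = 0.05
    batch_size: int = 8
    weight_decay: float = 0.01
    window: int = 2
    encoder_dim: int = 96
    seed: int = 0


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    shuffle: bool = True


def split_reports(reports: Sequence[Report], spec: SplitSpec) -> tuple[list[Report], list[Report]]:
    """Disjoint, exhaustive report-level split (unit = report)."""
    n = len(reports)
    idx = np.arange(n)
    if spec.shuffle:
        idx = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(round(spec.train_fraction * n))
    train_idx = set(idx[:n_train].tolist())
    train = [r for i, r in enumerate(reports) if i in train_idx]
    test = [r for i, r in enumerate(reports) if i not in train_idx]
    return train, test


def featurize_tokens(
    tokens: Sequence[str], encoder: HashingEncoder, window: int
) -> np.ndarray:
    """Feature row per token: concatenated embeddings of the token and its
    ±window neighbors; a zero padding vector stands in past the edges."""
    if window < 0:
        raise ValueError("window must be non-negative")
    n, dim = len(tokens), encoder.dim
    embs = encoder.encode(list(tokens)) if n else np.zeros((0, dim))
    width = 2 * window + 1
    out = np.zeros((n, width * dim), dtype=np.float64)
    for offset in range(-window, window + 1):
        col = (offset + window) * dim
        for i in range(n):
            j = i + offset
            if 0 <= j < n:
                out[i, col : col + dim] = embs[j]
    return out


@dataclass
class TokenTagger:
    """Trained reference tagger bundling encoder, window, and linear model."""

    config: NERConfig
    encoder: HashingEncoder
    model: SoftmaxRegression

    def predict_tags(self, tokens: Sequence[str]) -> list[str]:
        if not tokens:
            return []
        X = featurize_tokens(tokens, self.encoder, self.config.window)
        return [ID_TO_LABEL[int(i)] for i in self.model.predict(X)]


def _training_rows(
    reports: Sequence[Report], encoder: HashingEncoder, window: int
) -> tuple[np.ndarray, np.ndarray]:
    feats, labels = [], []
    for report in reports:
        sentences = report.sentences or [(0, len(report.text))]
        for sent in sentences:
            tagged = corpus_io.spans_to_bio(report, sent)
            if not tagged.tokens:
                continue
            feats.append(featurize_tokens(tagged.tokens, encoder, window))
            labels.extend(LABEL_TO_ID[t] for t in tagged.tags)
    if not feats:
        raise ValueError("no tokens in training reports")
    return np.vstack(feats), np.asarray(labels, dtype=int)


def train_tagger(reports: Sequence[Report], config: NERConfig | None = None) -> TokenTagger:
    """Train the windowed softmax tagger on BIO-converted reports."""
    config = config or NERConfig()
    if len(reports) < 2:
        raise ValueError("need at least 2 training reports")
    encoder = HashingEncoder(dim=config.encoder_dim, seed=config.seed)
    X, y = _training_rows(reports, encoder, config.window)
    present = {ID_TO_LABEL[int(l)] for l in np.unique(y)}
    missing = set(BIO_LABELS) - present
    if missing:
        warnings.warn(f"labels absent from training data: {sorted(missing)}")
    model = SoftmaxRegression(
        TrainConfig(
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            weight_decay=config.weight_decay,
            seed=config.seed,
        )
    )
    model.fit(X, y)
    return TokenTagger(config, encoder, model)


def tag_report(
    tagger: TokenTagger, report: Report
) -> tuple[list[TaggedSequence], list[EntityMention]]:
    """Tag every sentence; decode spans with BIO repair. Deterministic."""
    tagged_sentences: list[TaggedSequence] = []
    mentions: list[EntityMention] = []
    sentences = report.sentences or [(0, len(report.text))]
    for sent in sentences:
        tokens = corpus_io.sentence_tokens(report, sent)
        tags = tagger.predict_tags([t.text for t in tokens])
        tagged = TaggedSequence([t.text for t in tokens], tags)
        tagged_sentences.append(tagged)
        offsets = [(t.start, t.end) for t in tokens]
        mentions.extend(corpus_io.bio_to_spans(tagged, offsets, text=report.text))
    return tagged_sentences, mentions


def token_predictions(
    tagger: TokenTagger, reports: Sequence[Report]
) -> tuple[list[str], list[str]]:
    """Aligned (gold, predicted) BIO tag lists over all sentence tokens."""
    gold: list[str] = []
    pred: list[str] = []
    for report in reports:
        sentences = report.sentences or [(0, len(report.text))]
        for sent in sentences:
            tagged = corpus_io.spans_to_bio(report, sent)
            gold.extend(tagged.tags)
            pred.extend(tagger.predict_tags(tagged.tokens))
    return gold, pred
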