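"""Concept normalization: classification heads, routing, and fusion.

Each extracted mention is normalized per terminology.  Entity types route
to terminologies by what each terminology models: specimens to SNOMED CT,
test methods to LOINC, diagnoses to both SNOMED CT and ICD-11.  Per
terminology, a softmax classification head over mention embeddings
produces code probabilities; a retrieval channel (dense cosine or BM25)
proposes candidates from the full concept table; and a weighted fusion
with a confidence fallback picks the final code.  The fallback is what
handles codes the classifier never saw: when classifier confidence drops
below tau, the retrieval rank-1 wins outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import EntityMention, Report
from .encoders import Encoder
from .linear import SoftmaxRegression, TrainConfig
from .retrieval import (
    Candidate,
    CandidateSet,
    DenseIndex,
    SparseIndex,
    dense_search,
    sparse_search,
)
from .terminology import ConceptTable


def route_terminologies(entity_type: str) -> list[str]:
    """Terminologies a mention of this entity type is coded in."""
    routes = {
        "SAMPLE_TYPE": ["SNOMEDCT"],
        "TEST_PERFORMED": ["LOINC"],
        "FINDING": ["SNOMEDCT", "ICD11"],
    }
    if entity_type not in routes:
        raise ValueError(f"unknown entity type {entity_type!r}")
    return routes[entity_type]


@dataclass
class CoderConfig:
    """Code-classifier training: up to 10 epochs with early stopping once
    the validation loss (10% held-in split) fails to improve for 2
    consecutive epochs."""

    epochs: int = 10
    learning_rate: float = 0.05
    batch_size: int = 8
    weight_decay: float = 0.01
    val_fraction: float = 0.1
    patience: int = 2
    seed: int = 0


@dataclass
class CodeClassifier:
    """Per-terminology softmax head over mention embeddings."""

    terminology: str
    encoder: Encoder
    codes_: list[str] = field(default_factory=list)
    model: SoftmaxRegression | None = None

    def fit(self, texts: Sequence[str], gold_codes: Sequence[str],
            config: CoderConfig | None = None) -> "CodeClassifier":
        config = config or CoderConfig()
        if len(set(gold_codes)) < 2:
            raise ValueError("need at least 2 distinct codes to train")
        self.codes_ = sorted(set(gold_codes))
        code_to_idx = {c: i for i, c in enumerate(self.codes_)}
        X = self.encoder.encode(list(texts))
        y = np.asarray([code_to_idx[c] for c in gold_codes], dtype=int)
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(y))
        n_val = max(1, int(round(config.val_fraction * len(y))))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0 or len(set(y[train_idx].tolist())) < 2:
            train_idx, val_idx = order, order[:n_val]  # tiny data: train on all
        self.model = SoftmaxRegression(
            TrainConfig(
                epochs=config.epochs,
                learning_rate=config.learning_rate,
                batch_size=config.batch_size,
                weight_decay=config.weight_decay,
                seed=config.seed,
                patience=config.patience,
            )
        )
        self.model.fit(X[train_idx], y[train_idx], X[val_idx], y[val_idx])
        return self

    def predict_proba(self, texts: Sequence[str]) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not trained")
        return self.model.predict_proba(self.encoder.encode(list(texts)))


def fit_code_classifier(
    texts: Sequence[str],
    gold_codes: Sequence[str],
    terminology: str,
    encoder: Encoder,
    table: ConceptTable | None = None,
    config: CoderConfig | None = None,
) -> CodeClassifier:
    """Train a per-terminology head; gold codes must exist in *table* if given."""
    if table is not None:
        for code in gold_codes:
            if code not in table:
                raise ValueError(f"gold code {code!r} absent from {terminology} table")
    return CodeClassifier(terminology, encoder).fit(texts, gold_codes, config)


def classifier_candidates(model: CodeClassifier, text: str, k: int) -> CandidateSet:
    """Top-k codes by classifier probability."""
    probs = model.predict_proba([text])[0]
    if k > len(model.codes_):
        warnings.warn(
            f"k={k} exceeds label-space size {len(model.codes_)}; returning all"
        )
        k = len(model.codes_)
    scored = list(zip(model.codes_, probs.tolist()))
    return CandidateSet.from_scored(text, scored, source="classifier", k=k)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

@dataclass
class FusionConfig:
    """Fusion weight w in [0,1], confidence threshold tau in [0,1],
    candidate depth k >= 1."""

    w: float = 0.5
    tau: float = 0.3
    k: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0 and 0.0 <= self.tau <= 1.0 and self.k >= 1):
            raise ValueError("fusion config out of range")


def _sim01(candidates: CandidateSet) -> dict[str, float]:
    """Map retrieval scores onto [0, 1].

    Dense cosines map affinely via (s + 1) / 2.  BM25 scores are unbounded,
    so they are normalized by the max score within the candidate set (a
    monotone map, preserving ranks); an all-zero set maps to 0.
    """
    if not candidates.candidates:
        return {}
    source = candidates.candidates[0].source
    if source == "sparse":
        max_score = max(c.score for c in candidates.candidates)
        if max_score <= 0:
            return {c.code: 0.0 for c in candidates.candidates}
        return {c.code: c.score / max_score for c in candidates.candidates}
    return {c.code: float(np.clip((c.score + 1.0) / 2.0, 0.0, 1.0)) for c in candidates.candidates}


def fuse(
    clf: CandidateSet, retrieved: CandidateSet, cfg: FusionConfig
) -> tuple[str, CandidateSet]:
    """Weighted fusion with confidence fallback.

    Fused score s(c) = w * p_clf(c) + (1 - w) * sim01(c) over the union of
    candidate codes, with missing components read as 0.  Fallback: when the
    classifier's top probability is below tau, the retrieval rank-1 code is
    returned regardless of fused scores (retrieval overrides low-confidence
    classifier output).  Ties break to the lexicographically smaller code.
    """
    if not clf.candidates and not retrieved.candidates:
        raise ValueError("both candidate sets are empty")
    p_clf = {c.code: c.score for c in clf.candidates}
    sim = _sim01(retrieved)
    pool = sorted(set(p_clf) | set(sim))
    fused_scored = [
        (code, cfg.w * p_clf.get(code, 0.0) + (1.0 - cfg.w) * sim.get(code, 0.0))
        for code in pool
    ]
    fused = CandidateSet.from_scored(clf.query or retrieved.query, fused_scored, source="classifier")
    # the trail keeps provenance-tagged members rather than one source label
    fused.candidates = [
        Candidate(c.code, c.score, "fused") for c in fused.candidates
    ]
    max_conf = max(p_clf.values()) if p_clf else 0.0
    if max_conf < cfg.tau and retrieved.candidates:
        return retrieved.top().code, fused
    return fused.candidates[0].code, fused


def optimize_fusion(
    texts: Sequence[str],
    gold_codes: Sequence[str],
    terminology: str,
    table: ConceptTable,
    encoder: Encoder,
    index: DenseIndex | SparseIndex,
    grid_w: Sequence[float] | None = None,
    grid_tau: Sequence[float] | None = None,
    k: int = 5,
    seed: int = 0,
    coder_config: CoderConfig | None = None,
    n_folds: int = 5,
) -> FusionConfig:
    """Exhaustive (w, tau) grid search by mean 5-fold CV accuracy.

    Folds are seeded and stratified by code where possible (each code's
    occurrences are spread round-robin over folds).  Ties prefer smaller
    tau, then smaller w.  Candidates per fold are computed once and reused
    across the whole grid.
    """
    if len(texts) < n_folds:
        raise ValueError(f"need at least {n_folds} mentions")
    grid_w = list(grid_w) if grid_w is not None else [round(0.1 * i, 1) for i in range(11)]
    grid_tau = list(grid_tau) if grid_tau is not None else [round(0.1 * i, 1) for i in range(10)]
    rng = np.random.default_rng(seed)

    # stratified-by-code fold assignment
    folds = np.zeros(len(texts), dtype=int)
    by_code: dict[str, list[int]] = {}
    for i, code in enumerate(gold_codes):
        by_code.setdefault(code, []).append(i)
    for code in sorted(by_code):
        idxs = by_code[code]
        rng.shuffle(idxs)
        start = int(rng.integers(n_folds))
        for j, i in enumerate(idxs):
            folds[i] = (start + j) % n_folds

    texts = list(texts)
    gold = list(gold_codes)
    fold_pairs: list[list[tuple[CandidateSet, CandidateSet, str]]] = []
    for fold in range(n_folds):
        val_idx = [i for i in range(len(texts)) if folds[i] == fold]
        train_idx = [i for i in range(len(texts)) if folds[i] != fold]
        if not val_idx or len({gold[i] for i in train_idx}) < 2:
            continue
        clf = CodeClassifier(terminology, encoder).fit(
            [texts[i] for i in train_idx],
            [gold[i] for i in train_idx],
            coder_config or CoderConfig(seed=seed),
        )
        pairs = []
        for i in val_idx:
            clf_cs = classifier_candidates(clf, texts[i], k)
            if isinstance(index, DenseIndex):
                ret_cs = dense_search(index, texts[i], k, encoder)
            else:
                ret_cs = sparse_search(index, texts[i], k)
            pairs.append((clf_cs, ret_cs, gold[i]))
        fold_pairs.append(pairs)

    best: tuple[float, float, float] | None = None  # (-acc, tau, w)
    best_cfg = FusionConfig(w=1.0, tau=0.0, k=k)
    for tau in grid_tau:
        for w in grid_w:
            cfg = FusionConfig(w=w, tau=tau, k=k)
            accs = []
            for pairs in fold_pairs:
                correct = sum(
                    1 for clf_cs, ret_cs, g in pairs if fuse(clf_cs, ret_cs, cfg)[0] == g
                )
                accs.append(correct / len(pairs))
            key = (-float(np.mean(accs)) if accs else 0.0, tau, w)
            if best is None or key < best:
                best = key
                best_cfg = cfg
    return best_cfg


# ---------------------------------------------------------------------------
# End-to-end mention normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationResult:
    report_id: str
    mention: EntityMention
    terminology: str
    code: str
    source: str  # "fused" or "fallback"
    classifier_candidates: CandidateSet
    retrieval_candidates: CandidateSet
    fused_candidates: CandidateSet


def normalize_mentions(
    reports: Sequence[Report],
    classifiers: dict[str, CodeClassifier],
    indices: dict[str, DenseIndex | SparseIndex],
    fusion: dict[str, FusionConfig],
    encoder: Encoder,
) -> list[NormalizationResult]:
    """Fuse classifier and retrieval candidates for every routed mention."""
    results: list[NormalizationResult] = []
    for report in reports:
        for mention in report.entities:
            for term in route_terminologies(mention.entity_type):
                if term not in classifiers or term not in indices:
                    raise ValueError(f"missing model or index for terminology {term}")
                cfg = fusion.get(term, FusionConfig())
                clf_cs = classifier_candidates(classifiers[term], mention.surface, cfg.k)
                index = indices[term]
                if isinstance(index, DenseIndex):
                    ret_cs = dense_search(index, mention.surface, cfg.k, encoder)
                else:
                    ret_cs = sparse_search(index, mention.surface, cfg.k)
                code, fused_cs = fuse(clf_cs, ret_cs, cfg)
                max_conf = max((c.score for c in clf_cs.candidates), default=0.0)
                source = "fallback" if max_conf < cfg.tau else "fused"
                results.append(
                    NormalizationResult(
                        report.report_id, mention, term, code, source,
                        clf_cs, ret_cs, fused_cs,
                    )
                )
    return results
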