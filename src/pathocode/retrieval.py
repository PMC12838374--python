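"""Candidate retrieval over terminology entries.

Two channels: exhaustive dense cosine nearest-neighbor search over encoded
entries, and Okapi BM25 sparse lexical search.  Every concept contributes
one entry per label and per synonym; a code's score is the max over its
entries (concatenating synonyms into one document dilutes rare surface
forms and was rejected).  Dense scores are raw cosines; any rescaling is
the fusion layer's business.
"""

from __future__ import annotations

import json
import math
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import word_tokenize
from .encoders import Encoder
from .terminology import ConceptTable, text_entries


@dataclass(frozen=True)
class Candidate:
    code: str
    score: float
    source: str  # classifier | dense | sparse


@dataclass
class CandidateSet:
    """Ranked unique-code candidates, scores non-increasing.

    When several raw (code, score) pairs share a code, the best score is
    kept.  Ties in score are broken by lexicographically smaller code.
    """

    query: str
    candidates: list[Candidate] = field(default_factory=list)

    @classmethod
    def from_scored(
        cls, query: str, scored: Sequence[tuple[str, float]], source: str, k: int | None = None
    ) -> "CandidateSet":
        best: dict[str, float] = {}
        for code, score in scored:
            if code not in best or score > best[code]:
                best[code] = float(score)
        ranked = sorted(best.items(), key=lambda cs: (-cs[1], cs[0]))
        if k is not None:
            ranked = ranked[:k]
        return cls(query, [Candidate(c, s, source) for c, s in ranked])

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.candidates]

    def top(self) -> Candidate:
        if not self.candidates:
            raise ValueError("empty candidate set")
        return self.candidates[0]

    def score_of(self, code: str) -> float | None:
        for cand in self.candidates:
            if cand.code == code:
                return cand.score
        return None


# ---------------------------------------------------------------------------
# Dense index
# ---------------------------------------------------------------------------

@dataclass
class DenseIndex:
    matrix: np.ndarray  # (n_entries, dim), unit-norm rows
    entries: list[tuple[str, str]]  # (entry_text, code)
    fingerprint: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.entries):
            raise ValueError("matrix row count must equal entry count")
        norms = np.linalg.norm(self.matrix, axis=1)
        if self.matrix.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("index rows must be unit-norm")


def build_dense_index(table: ConceptTable, encoder: Encoder) -> DenseIndex:
    entries = text_entries(table)
    if not entries:
        raise ValueError("cannot index an empty concept table")
    matrix = encoder.encode([text for text, _ in entries])
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return DenseIndex(matrix / norms, entries, encoder.fingerprint())


def dense_search(index: DenseIndex, query_text: str, k: int, encoder: Encoder) -> CandidateSet:
    """Top-k codes by maximum cosine over each code's entries (exhaustive)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if not index.entries:
        raise ValueError("empty index")
    if encoder.fingerprint() != index.fingerprint:
        raise ValueError("encoder fingerprint does not match the index")
    q = encoder.encode([query_text])[0]
    qn = np.linalg.norm(q)
    if qn > 0:
        q = q / qn
    sims = index.matrix @ q
    scored = [(code, float(sims[i])) for i, (_, code) in enumerate(index.entries)]
    return CandidateSet.from_scored(query_text, scored, source="dense", k=k)


def save_dense_index(index: DenseIndex, path: str | Path) -> None:
    """Persist as a directory: entry matrix (npy), entry table (TSV), manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "matrix.npy", index.matrix)
    with open(path / "entries.tsv", "w", encoding="utf-8") as fh:
        for text, code in index.entries:
            fh.write(f"{text}\t{code}\n")
    manifest = {"fingerprint": index.fingerprint, "built": time.strftime("%Y-%m-%dT%H:%M:%S")}
    (path / "manifest.json").write_text(json.dumps(manifest))


def load_dense_index(path: str | Path) -> DenseIndex:
    path = Path(path)
    matrix = np.load(path / "matrix.npy")
    entries = []
    with open(path / "entries.tsv", encoding="utf-8") as fh:
        for line in fh:
            text, code = line.rstrip("\n").split("\t")
            entries.append((text, code))
    manifest = json.loads((path / "manifest.json").read_text())
    return DenseIndex(matrix, entries, manifest["fingerprint"])


# ---------------------------------------------------------------------------
# Sparse (Okapi BM25) index
# ---------------------------------------------------------------------------

def bm25_tokenize(text: str) -> list[str]:
    """Lowercased word tokens, same word segmentation as the corpus tokenizer."""
    return [tok.text.lower() for tok in word_tokenize(text)]


@dataclass
class SparseIndex:
    entries: list[tuple[str, str]]  # (entry_text, code)
    token_counts: list[Counter]
    doc_freq: Counter
    avg_len: float
    k1: float = 1.5
    b: float = 0.75

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if not (0.0 <= self.b <= 1.0):
            raise ValueError("b must lie in [0, 1]")


def build_sparse_index(table: ConceptTable, k1: float = 1.5, b: float = 0.75) -> SparseIndex:
    entries = text_entries(table)
    if not entries:
        raise ValueError("cannot index an empty concept table")
    token_counts = [Counter(bm25_tokenize(text)) for text, _ in entries]
    doc_freq: Counter = Counter()
    for counts in token_counts:
        doc_freq.update(counts.keys())
    lengths = [sum(c.values()) for c in token_counts]
    avg_len = float(np.mean(lengths)) if lengths else 0.0
    return SparseIndex(entries, token_counts, doc_freq, avg_len, k1, b)


def bm25_score(index: SparseIndex, query_tokens: Sequence[str], entry_id: int) -> float:
    """Okapi BM25 with idf(t) = ln((N - df + 0.5)/(df + 0.5) + 1).

    The +1 inside the log keeps idf non-negative.  Query terms absent from
    the entry contribute 0.
    """
    counts = index.token_counts[entry_id]
    doc_len = sum(counts.values())
    n_docs = len(index.entries)
    score = 0.0
    for term in query_tokens:
        tf = counts.get(term, 0)
        if tf == 0:
            continue
        df = index.doc_freq[term]
        idf = math.log((n_docs - df + 0.5) / (df + 0.5) + 1.0)
        denom = tf + index.k1 * (1.0 - index.b + index.b * doc_len / index.avg_len)
        score += idf * tf * (index.k1 + 1.0) / denom
    return score


def sparse_search(index: SparseIndex, query_text: str, k: int) -> CandidateSet:
    """Top-k codes by maximum BM25 over each code's entries."""
    if k < 1:
        raise ValueError("k must be at least 1")
    query_tokens = bm25_tokenize(query_text)
    if not query_tokens:
        return CandidateSet(query_text, [])
    scored = [
        (code, bm25_score(index, query_tokens, i))
        for i, (_, code) in enumerate(index.entries)
    ]
    return CandidateSet.from_scored(query_text, scored, source="sparse", k=k)
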