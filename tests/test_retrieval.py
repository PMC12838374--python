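"""Dense and BM25 sparse search against exhaustive oracles."""

import math
from collections import Counter

import numpy as np
import pytest

from pathocode.encoders import HashingEncoder
from pathocode.retrieval import (
    CandidateSet,
    bm25_score,
    bm25_tokenize,
    build_dense_index,
    build_sparse_index,
    dense_search,
    load_dense_index,
    save_dense_index,
    sparse_search,
)
from pathocode.terminology import Concept, from_concepts


def _table(entries):
    """entries: list of (code, label, synonyms)."""
    return from_concepts("LOINC", [
        Concept("LOINC", code, label, list(syns), "PATH") for code, label, syns in entries
    ])


@pytest.fixture(scope="module")
def encoder():
    return HashingEncoder(dim=128, seed=4)


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(17)
    words = ["thyroid", "biopsy", "stain", "lung", "marrow", "cell", "node",
             "tissue", "tumor", "acid", "blue", "red", "silver", "smear"]
    entries = []
    for i in range(100):
        label = " ".join(rng.choice(words, size=rng.integers(1, 4)))
        entries.append((f"{1000+i}-{i % 10}", f"{label} {i}", []))
    return _table(entries)


class TestDense:
    def test_exact_entry_ranks_first_with_unit_score(self, encoder):
        table = _table([("1-1", "thyroid biopsy", []), ("2-2", "giemsa stain", [])])
        index = build_dense_index(table, encoder)
        result = dense_search(index, "giemsa stain", k=2, encoder=encoder)
        assert result.top().code == "2-2"
        assert result.top().score == pytest.approx(1.0, abs=1e-6)

    def test_k_larger_than_codes_returns_all(self, encoder):
        table = _table([("1-1", "a b", []), ("2-2", "c d", [])])
        index = build_dense_index(table, encoder)
        assert len(dense_search(index, "a", k=10, encoder=encoder)) == 2

    def test_rebuild_is_bit_identical(self, encoder, tmp_path):
        table = _table([("1-1", "thyroid biopsy", ["biopsy of thyroid"])])
        i1 = build_dense_index(table, encoder)
        i2 = build_dense_index(table, encoder)
        np.testing.assert_array_equal(i1.matrix, i2.matrix)
        save_dense_index(i1, tmp_path / "idx")
        loaded = load_dense_index(tmp_path / "idx")
        np.testing.assert_array_equal(loaded.matrix, i1.matrix)
        assert loaded.entries == i1.entries

    def test_rows_equal_encoder_output(self, encoder):
        table = _table([("1-1", "thyroid biopsy", ["biopsy of thyroid"])])
        index = build_dense_index(table, encoder)
        np.testing.assert_allclose(
            index.matrix, encoder.encode([t for t, _ in index.entries]), atol=1e-12
        )

    def test_matches_exhaustive_cosine_oracle(self, encoder, random_table):
        index = build_dense_index(random_table, encoder)
        rng = np.random.default_rng(8)
        words = ["thyroid", "stain", "node", "tumor", "silver", "cell"]
        for _ in range(30):
            query = " ".join(rng.choice(words, size=rng.integers(1, 3)))
            got = dense_search(index, query, k=5, encoder=encoder)
            q = encoder.encode([query])[0]
            best = {}
            for (text, code), row in zip(index.entries, index.matrix):
                sim = float(np.dot(q, row))
                if code not in best or sim > best[code]:
                    best[code] = sim
            want = sorted(best.items(), key=lambda cs: (-cs[1], cs[0]))[:5]
            assert [(c.code) for c in got] == [c for c, _ in want]
            np.testing.assert_allclose([c.score for c in got],
                                       [s for _, s in want], atol=1e-9)

    def test_fingerprint_mismatch_rejected(self, encoder):
        table = _table([("1-1", "a", [])])
        index = build_dense_index(table, encoder)
        other = HashingEncoder(dim=128, seed=99)
        with pytest.raises(ValueError, match="fingerprint"):
            dense_search(index, "a", 1, other)


class TestBM25:
    def test_no_shared_terms_scores_zero(self):
        table = _table([("1-1", "giemsa stain", [])])
        index = build_sparse_index(table)
        assert bm25_score(index, ["thyroid"], 0) == 0.0

    def test_duplicate_entries_score_equally(self):
        table = _table([("1-1", "thyroid biopsy", []), ("2-2", "thyroid biopsy", [])])
        index = build_sparse_index(table)
        q = ["thyroid"]
        assert bm25_score(index, q, 0) == bm25_score(index, q, 1)

    def test_hand_computed_toy_corpus_value(self):
        # 3 entries, query {thyroid, biopsy}; value frozen from the stated
        # formula evaluated by hand before implementation.
        table = _table([
            ("1-1", "thyroid biopsy", []),
            ("2-2", "thyroid stain", []),
            ("3-3", "bone marrow sample", []),
        ])
        index = build_sparse_index(table)
        got = bm25_score(index, ["thyroid", "biopsy"], 0)
        assert got == pytest.approx(1.5505084237866003, abs=1e-9)
        assert bm25_score(index, ["thyroid", "biopsy"], 1) == pytest.approx(
            0.5022939549191067, abs=1e-9
        )

    def test_unique_entry_query_ranks_first(self):
        table = _table([
            ("1-1", "giemsa stain", []),
            ("2-2", "thyroid biopsy", []),
        ])
        index = build_sparse_index(table)
        assert sparse_search(index, "thyroid biopsy", 2).top().code == "2-2"

    def test_empty_query_after_tokenization(self):
        table = _table([("1-1", "a", [])])
        index = build_sparse_index(table)
        assert len(sparse_search(index, "   ", 3)) == 0

    def test_matches_exhaustive_scoring_oracle(self, random_table):
        index = build_sparse_index(random_table)
        rng = np.random.default_rng(21)
        words = ["thyroid", "stain", "node", "tumor", "silver", "cell", "zz"]
        for _ in range(30):
            query = " ".join(rng.choice(words, size=rng.integers(1, 4)))
            got = sparse_search(index, query, k=5)
            tokens = bm25_tokenize(query)
            best = {}
            for i, (_, code) in enumerate(index.entries):
                s = bm25_score(index, tokens, i)
                if code not in best or s > best[code]:
                    best[code] = s
            want = sorted(best.items(), key=lambda cs: (-cs[1], cs[0]))[:5]
            assert got.codes == [c for c, _ in want]

    def test_idf_shift_after_adding_entry_is_explained_by_df(self):
        base = _table([("1-1", "thyroid biopsy", []), ("2-2", "giemsa stain", [])])
        extended = _table([
            ("1-1", "thyroid biopsy", []),
            ("2-2", "giemsa stain", []),
            ("3-3", "lung smear", []),
        ])
        i1, i2 = build_sparse_index(base), build_sparse_index(extended)
        # recompute the expected shift for an unrelated code from N and df
        for idx, (index, n) in enumerate([(i1, 2), (i2, 3)]):
            counts = Counter(bm25_tokenize("giemsa stain"))
            df = index.doc_freq["giemsa"]
            idf = math.log((n - df + 0.5) / (df + 0.5) + 1)
            expected = idf * 1 * 2.5 / (1 + 1.5 * (1 - 0.75 + 0.75 * 2 / index.avg_len))
            assert bm25_score(index, ["giemsa"], 1) == pytest.approx(expected)


class TestCandidateSet:
    def test_scores_non_increasing_and_codes_unique(self):
        cs = CandidateSet.from_scored(
            "q", [("b", 0.5), ("a", 0.9), ("b", 0.8), ("c", 0.9)], "dense"
        )
        scores = [c.score for c in cs]
        assert scores == sorted(scores, reverse=True)
        assert len(set(cs.codes)) == len(cs.codes)
        # tie at 0.9 broken lexicographically; best score per code kept
        assert cs.codes == ["a", "c", "b"]

    def test_invalid_k_rejected(self, encoder):
        table = _table([("1-1", "a", [])])
        index = build_dense_index(table, encoder)
        with pytest.raises(ValueError):
            dense_search(index, "a", 0, encoder)
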