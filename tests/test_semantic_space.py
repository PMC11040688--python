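"""Vocabulary ranking, co-occurrence counting, and SVD compression."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from witsem import (
    CooccurrenceMatrix,
    NGramCorpus,
    SemanticSpace,
    SimulationConfig,
    build_cooccurrence,
    build_space,
    build_vocabulary,
    extract_ngrams,
    log_transform,
    simulate_corpus,
    svd_compress,
)
from witsem.corpus_io import make_tokenizer


def _corpus(n, *grams):
    corpus = NGramCorpus(n)
    for tokens, count in grams:
        corpus.add(tuple(tokens.split()), count)
    return corpus


# ---------------------------------------------------------------------------
# n-gram extraction
# ---------------------------------------------------------------------------


def test_extract_ngrams_worked_example():
    grams = extract_ngrams("He was wearing a blue jacket", 3)
    assert grams == [
        ("he", "was", "wearing"),
        ("was", "wearing", "a"),
        ("wearing", "a", "blue"),
        ("a", "blue", "jacket"),
    ]


@pytest.mark.parametrize(
    "text, n, expected_count",
    [("a b", 3, 0), ("a b c d e", 5, 1), ("a b c", 1, 3)],
)
def test_extract_ngrams_window_count(text, n, expected_count):
    assert len(extract_ngrams(text, n)) == expected_count


def test_extract_ngrams_invalid_n():
    with pytest.raises(ValueError):
        extract_ngrams("a b c", 0)


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------


def test_vocabulary_frequencies_weighted_by_gram_count():
    vocab = build_vocabulary(_corpus(5, ("a a b c d", 2)), R=4, C=4)
    assert vocab.frequencies == {"a": 4, "b": 2, "c": 2, "d": 2}
    assert vocab.row_words[0] == "a"


def test_vocabulary_truncation_and_warning():
    corpus = _corpus(3, ("a b c", 1))
    with pytest.warns(UserWarning, match="distinct words"):
        vocab = build_vocabulary(corpus, R=10, C=10)
    assert set(vocab.row_words) == {"a", "b", "c"}


def test_vocabulary_tie_break_is_lexicographic():
    corpus = _corpus(3, ("b c a", 1), ("c a b", 1))
    vocab = build_vocabulary(corpus, R=3, C=3)
    assert vocab.row_words == ("a", "b", "c")  # equal freq -> lexicographic


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------


def _cell(mat, r, c):
    return mat.values[mat.row_words.index(r), mat.col_words.index(c)]


def test_cooccurrence_distinct_words():
    corpus = _corpus(5, ("a b c d e", 2))
    mat = build_cooccurrence(corpus, build_vocabulary(corpus, 5, 5))
    assert _cell(mat, "a", "b") == 2
    assert _cell(mat, "b", "a") == 2
    assert _cell(mat, "a", "a") == 0


def test_cooccurrence_repeated_word():
    corpus = _corpus(3, ("a a b", 1))
    mat = build_cooccurrence(corpus, build_vocabulary(corpus, 2, 2))
    assert _cell(mat, "a", "a") == 2  # two ordered distinct-position pairs
    assert _cell(mat, "a", "b") == 2
    assert _cell(mat, "b", "a") == 2


def test_cooccurrence_empty_corpus_zero_matrix():
    vocab = build_vocabulary(_corpus(3, ("a b c", 1)), 3, 3)
    mat = build_cooccurrence(NGramCorpus(3), vocab)
    assert not mat.values.any()


@settings(max_examples=20, deadline=None)
@given(
    grams=st.lists(
        st.tuples(
            st.lists(st.sampled_from("abcd"), min_size=3, max_size=3),
            st.integers(1, 5),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_cooccurrence_matches_pair_enumeration(grams):
    """Matrix equals a brute-force enumeration of ordered position pairs."""
    corpus = NGramCorpus(3)
    for tokens, count in grams:
        corpus.add(tuple(tokens), count)
    vocab = build_vocabulary(corpus, 4, 4)
    mat = build_cooccurrence(corpus, vocab)
    expected = np.zeros_like(mat.values)
    for tokens, count in corpus.items():
        for i, ti in enumerate(tokens):
            for j, tj in enumerate(tokens):
                if i != j:
                    expected[
                        vocab.row_index[ti], vocab.col_index[tj]
                    ] += count
    np.testing.assert_array_equal(mat.values, expected)


def test_unordered_convention_halves_pairs():
    corpus = _corpus(3, ("a b c", 4))
    vocab = build_vocabulary(corpus, 3, 3)
    ordered = build_cooccurrence(corpus, vocab, pairs="ordered")
    unordered = build_cooccurrence(corpus, vocab, pairs="unordered")
    assert _cell(ordered, "a", "b") == 4
    assert _cell(unordered, "a", "b") == 4
    assert _cell(unordered, "b", "a") == 0  # attributed to the earlier position


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------


def test_log_transform_values_and_double_transform():
    corpus = _corpus(3, ("a b c", 1))
    vocab = build_vocabulary(corpus, 3, 3)
    mat = build_cooccurrence(corpus, vocab)
    raw = mat.values.copy()
    raw[0, 0] = np.e - 1.0
    mat = CooccurrenceMatrix(raw, mat.row_words, mat.col_words, "raw")
    out = log_transform(mat)
    assert out.values[0, 0] == pytest.approx(1.0)
    assert out.values[raw == 0].sum() == 0.0  # log(1+0) = 0
    # monotone elementwise
    order = np.argsort(raw, axis=None)
    assert (np.diff(out.values.flat[order]) >= 0).all()
    with pytest.raises(ValueError, match="already"):
        log_transform(out)


# ---------------------------------------------------------------------------
# SVD compression
# ---------------------------------------------------------------------------


def _matrix(values):
    values = np.asarray(values, dtype=float)
    rows = tuple(f"r{i}" for i in range(values.shape[0]))
    cols = tuple(f"c{j}" for j in range(values.shape[1]))
    return CooccurrenceMatrix(values, rows, cols, "log1p")


def test_rank_one_matrix_compresses_exactly():
    u = np.array([1.0, 2.0, 3.0, 4.0])
    v = np.array([2.0, 1.0, 0.5, 0.25])
    mat = _matrix(np.outer(u, v))
    space = svd_compress(mat, 1)
    # rank-1: truncation is exact, all vectors are +-1 scalars
    dots = space.matrix @ space.matrix.T
    assert np.allclose(np.abs(dots), 1.0, atol=1e-12)


def test_word_vectors_are_unit_norm(space):
    norms = np.linalg.norm(space.matrix, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-9)


def test_identity_matrix_gives_orthogonal_vectors():
    space = svd_compress(_matrix(np.eye(3)), 3)
    np.testing.assert_allclose(space.matrix @ space.matrix.T, np.eye(3), atol=1e-12)


def test_svd_dimension_bound():
    with pytest.raises(ValueError, match="d must be"):
        svd_compress(_matrix(np.eye(3)), 4)


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 10_000), st.integers(1, 4))
def test_truncation_optimality_vs_full_svd(seed, d):
    """Rank-d reconstruction error matches the full-SVD truncation oracle."""
    from scipy.linalg import svd as scipy_svd

    from witsem import svd_preprocess

    rng = np.random.default_rng(seed)
    values = rng.gamma(1.0, 2.0, size=(6, 5))
    svd = svd_preprocess(values)
    our_err = np.linalg.norm(
        values - svd.scores[:, :d] @ svd.basis[:, :d].T, "fro"
    )
    U, S, Vt = scipy_svd(values, full_matrices=False)
    oracle_err = np.linalg.norm(values - (U[:, :d] * S[:d]) @ Vt[:d], "fro")
    assert our_err == pytest.approx(oracle_err, abs=1e-8)


def test_all_zero_rows_are_dropped():
    values = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
    with pytest.warns(UserWarning, match="all-zero"):
        space = svd_compress(_matrix(values), 2)
    assert space.words == ("r0", "r2")


def test_cluster_recovery(bundle, space):
    """Planted word clusters: within-cluster similarity > between-cluster."""
    clusters = bundle.clusters
    within, between = [], []
    words = [w for w in space.words if w in clusters]
    rng = np.random.default_rng(0)
    pick = rng.choice(len(words), size=(400, 2))
    for i, j in pick:
        if i == j:
            continue
        dot = float(space.vector(words[i]) @ space.vector(words[j]))
        (within if clusters[words[i]] == clusters[words[j]] else between).append(dot)
    assert np.mean(within) > np.mean(between)


def test_space_determinism_and_serialisation(bundle, space, tmp_path):
    rebuilt = build_space(bundle.corpus, R=240, C=240, d=80)
    np.testing.assert_array_equal(rebuilt.matrix, space.matrix)
    assert rebuilt.words == space.words

    path = tmp_path / "space.tsv"
    space.save(path)
    loaded = SemanticSpace.load(path)
    assert loaded.words == space.words
    np.testing.assert_array_equal(loaded.matrix, space.matrix)


def test_zero_leakage_has_no_between_cluster_cooccurrence():
    cfg = SimulationConfig(seed=5, leakage=0.0, n_grams=2_000, vocab_size=130)
    corpus, clusters = simulate_corpus(cfg)
    vocab = build_vocabulary(corpus, 130, 130)
    mat = build_cooccurrence(corpus, vocab)
    for i, r in enumerate(mat.row_words):
        for j, c in enumerate(mat.col_words):
            if clusters[r] != clusters[c]:
                assert mat.values[i, j] == 0.0
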