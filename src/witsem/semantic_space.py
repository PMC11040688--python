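"""Construction of the LSA semantic space from an n-gram corpus.

The space is built in four steps:

1. frequency-ranked vocabularies — the R most frequent words index the
   rows and the C most frequent words the columns of the co-occurrence
   matrix (the full-scale configuration is R = 50,000, C = 120,000);
2. a co-occurrence matrix over the corpus grams — cell (r, c) counts how
   often row word r and column word c occur together within a gram;
3. an elementwise log(1 + x) transform of the counts;
4. a truncated SVD — each row word is represented by the first d
   coordinates of U·S (left singular vectors scaled by singular
   values), and the resulting vector is normalised to unit length so
   that dot products between word vectors are cosines in [-1, +1].

Co-occurrence "together within a gram" is not uniquely defined; the
default convention counts ordered pairs of distinct positions, which
makes cell(a, b) = cell(b, a) for distinct words, and is configurable
(unordered pairs, or a maximum positional distance).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .corpus_io import NGramCorpus, Tokenizer, default_tokenizer

__all__ = [
    "DEFAULT_ROW_VOCAB",
    "DEFAULT_COL_VOCAB",
    "DEFAULT_DIMENSIONS",
    "Vocabulary",
    "CooccurrenceMatrix",
    "SemanticSpace",
    "extract_ngrams",
    "build_vocabulary",
    "build_cooccurrence",
    "log_transform",
    "svd_compress",
    "build_space",
    "fix_svd_signs",
]

#: Full-scale defaults for a web-scale n-gram corpus.  Desk-scale corpora
#: simply have fewer distinct words, in which case the whole vocabulary
#: is used (with a warning).
DEFAULT_ROW_VOCAB = 50_000
DEFAULT_COL_VOCAB = 120_000
DEFAULT_DIMENSIONS = 300


# ---------------------------------------------------------------------------
# n-gram extraction
# ---------------------------------------------------------------------------


def extract_ngrams(
    text: str | list[str],
    n: int,
    tokenizer: Tokenizer | None = None,
) -> list[tuple[str, ...]]:
    """All consecutive n-token windows of a text, in order.

    A text of T tokens yields max(0, T - n + 1) grams; e.g. a six-word
    sentence yields four 3-grams.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    tokens = (tokenizer or default_tokenizer)(text) if isinstance(text, str) else list(text)
    return [tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Vocabulary:
    """Frequency-ranked row and column word lists.

    Both lists are sorted by descending corpus frequency with a
    lexicographic tie-break, so vocabulary construction is deterministic
    across runs.
    """

    row_words: tuple[str, ...]
    col_words: tuple[str, ...]
    frequencies: Mapping[str, int]
    row_index: Mapping[str, int] = field(init=False, repr=False, compare=False)
    col_index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "row_index", {w: i for i, w in enumerate(self.row_words)}
        )
        object.__setattr__(
            self, "col_index", {w: i for i, w in enumerate(self.col_words)}
        )


def build_vocabulary(corpus: NGramCorpus, R: int, C: int) -> Vocabulary:
    """Select the top-R row words and top-C column words by frequency.

    A word's frequency is its total token-occurrence count: the sum over
    grams of (gram count x occurrences of the word in that gram).  If the
    corpus has fewer distinct words than requested, all words are used
    and a warning is emitted.
    """
    if R < 1 or C < 1:
        raise ValueError("R and C must be >= 1")
    freq: Counter[str] = Counter()
    for tokens, count in corpus.items():
        for tok in tokens:
            freq[tok] += count
    ranked = sorted(freq, key=lambda w: (-freq[w], w))
    if len(ranked) < max(R, C):
        warnings.warn(
            f"corpus has only {len(ranked)} distinct words "
            f"(requested R={R}, C={C}); using all of them",
            stacklevel=2,
        )
    return Vocabulary(
        row_words=tuple(ranked[:R]),
        col_words=tuple(ranked[:C]),
        frequencies=dict(freq),
    )


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """R x C co-occurrence counts (raw) or their log(1+x) transform."""

    values: np.ndarray
    row_words: tuple[str, ...]
    col_words: tuple[str, ...]
    transform: str = "raw"  # "raw" | "log1p"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_words), len(self.col_words)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match vocabulary "
                f"({len(self.row_words)} x {len(self.col_words)})"
            )
        if self.transform not in ("raw", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")


def build_cooccurrence(
    corpus: NGramCorpus,
    vocab: Vocabulary,
    pairs: str = "ordered",
    max_distance: int | None = None,
) -> CooccurrenceMatrix:
    """Accumulate within-gram co-occurrence counts into an R x C matrix.

    With the default ``pairs="ordered"`` convention, cell (r, c) sums
    gram count x the number of ordered pairs of distinct positions
    (i, j) with token_i = r and token_j = c; a word repeated within a
    gram therefore co-occurs with itself.  ``pairs="unordered"`` counts
    each unordered position pair once (i < j, attributed row=token_i).
    ``max_distance`` restricts pairs to |i - j| <= max_distance.
    Words outside the respective vocabulary are ignored.
    """
    if pairs not in ("ordered", "unordered"):
        raise ValueError(f"unknown pair convention {pairs!r}")
    row_index = vocab.row_index
    col_index = vocab.col_index
    values = np.zeros((len(vocab.row_words), len(vocab.col_words)), dtype=np.float64)
    for tokens, count in corpus.items():
        rows = [row_index.get(t) for t in tokens]
        cols = [col_index.get(t) for t in tokens]
        m = len(tokens)
        for i in range(m):
            for j in range(m):
                if i == j:
                    continue
                if pairs == "unordered" and j < i:
                    continue
                if max_distance is not None and abs(i - j) > max_distance:
                    continue
                r, c = rows[i], cols[j]
                if r is not None and c is not None:
                    values[r, c] += count
    return CooccurrenceMatrix(
        values=values,
        row_words=vocab.row_words,
        col_words=vocab.col_words,
        transform="raw",
    )


def log_transform(matrix: CooccurrenceMatrix) -> CooccurrenceMatrix:
    """Elementwise x -> ln(1 + x).  Applying it twice is an error."""
    if matrix.transform != "raw":
        raise ValueError("matrix is already log1p-transformed")
    return CooccurrenceMatrix(
        values=np.log1p(matrix.values),
        row_words=matrix.row_words,
        col_words=matrix.col_words,
        transform="log1p",
    )


# ---------------------------------------------------------------------------
# SVD compression
# ---------------------------------------------------------------------------


def fix_svd_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the per-component sign ambiguity of an SVD.

    Each left singular vector is flipped so that its largest-magnitude
    component is positive (ties broken by the lowest index, which is
    what argmax returns); the matching right singular vector is flipped
    with it so U S Vt is unchanged.  Downstream statistics are invariant
    to these flips; fixing them makes serialised spaces byte-stable.
    """
    U = U.copy()
    Vt = Vt.copy()
    for j in range(U.shape[1]):
        idx = int(np.argmax(np.abs(U[:, j])))
        if U[idx, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return U, Vt


class SemanticSpace:
    """Unit-norm d-dimensional vectors for a set of words.

    Parameters
    ----------
    words:
        Vocabulary of the space, aligned with the rows of ``matrix``.
    matrix:
        (W x d) array; every row must have unit L2 norm (1e-9).
    metadata:
        Construction provenance (R, C, d, transform, corpus id, ...),
        round-tripped through serialisation.
    """

    def __init__(
        self,
        words: Iterable[str],
        matrix: np.ndarray,
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        self.words: tuple[str, ...] = tuple(words)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.words):
            raise ValueError("matrix must be (n_words x d)")
        norms = np.linalg.norm(self.matrix, axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-9):
            worst = self.words[int(np.argmax(np.abs(norms - 1.0)))]
            raise ValueError(f"word vectors must be unit-norm (violated by {worst!r})")
        self.metadata: dict[str, object] = dict(metadata or {})
        self._index = {w: i for i, w in enumerate(self.words)}

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        return self.matrix[self._index[word]]

    def get(self, word: str) -> np.ndarray | None:
        i = self._index.get(word)
        return None if i is None else self.matrix[i]

    # -- serialisation ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the space as TSV with ``#key=value`` header lines."""
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            meta = {"d": self.d, **self.metadata}
            for key in sorted(meta):
                fh.write(f"#{key}={meta[key]}\n")
            for word, vec in zip(self.words, self.matrix):
                fh.write(word + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SemanticSpace":
        path = Path(path)
        metadata: dict[str, object] = {}
        words: list[str] = []
        rows: list[list[float]] = []
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].partition("=")
                    metadata[key] = value
                    continue
                parts = line.split("\t")
                words.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        metadata.pop("d", None)
        return cls(words, np.array(rows, dtype=np.float64), metadata)


def svd_compress(
    matrix: CooccurrenceMatrix,
    d: int,
    word_vectors: str = "us",
) -> SemanticSpace:
    """Compress a (transformed) co-occurrence matrix into a d-dim space.

    Row word r is represented by the r-th row of U_d S_d (``"us"``, the
    default) or of U_d (``"u"``), then normalised to unit length.  Rows
    that are entirely zero (the word never co-occurs with any column
    word) carry no information and are dropped with a warning.
    """
    if word_vectors not in ("us", "u"):
        raise ValueError(f"unknown word_vectors convention {word_vectors!r}")
    R, C = matrix.values.shape
    if not 1 <= d <= min(R, C):
        raise ValueError(f"d must be in [1, {min(R, C)}], got {d}")
    if matrix.transform == "raw":
        warnings.warn(
            "compressing a raw (untransformed) co-occurrence matrix", stacklevel=2
        )
    U, S, Vt = np.linalg.svd(matrix.values, full_matrices=False)
    U, Vt = fix_svd_signs(U, Vt)
    vectors = U[:, :d] * S[:d] if word_vectors == "us" else U[:, :d]
    norms = np.linalg.norm(matrix.values, axis=1)
    keep = norms > 0
    if not np.all(keep):
        dropped = [w for w, k in zip(matrix.row_words, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} all-zero row words from the space "
            f"(first few: {dropped[:5]})",
            stacklevel=2,
        )
    vectors = vectors[keep]
    vec_norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    # a row can be numerically zero after truncation even if its raw row
    # was not; guard and drop those too
    nonzero = vec_norms[:, 0] > 0
    words = [w for w, k in zip(matrix.row_words, keep) if k]
    if not np.all(nonzero):
        dropped = [w for w, k in zip(words, nonzero) if not k]
        warnings.warn(
            f"dropping {len(dropped)} words with zero-norm truncated vectors",
            stacklevel=2,
        )
        vectors = vectors[nonzero]
        words = [w for w, k in zip(words, nonzero) if k]
        vec_norms = vec_norms[nonzero]
    return SemanticSpace(
        words,
        vectors / vec_norms,
        metadata={
            "R": R,
            "C": C,
            "transform": matrix.transform,
            "word_vectors": word_vectors,
        },
    )


def build_space(
    corpus: NGramCorpus,
    R: int = DEFAULT_ROW_VOCAB,
    C: int = DEFAULT_COL_VOCAB,
    d: int = DEFAULT_DIMENSIONS,
    pairs: str = "ordered",
    word_vectors: str = "us",
) -> SemanticSpace:
    """Convenience pipeline: vocabulary -> co-occurrence -> log1p -> SVD.

    ``d`` is capped at the matrix rank bound when the corpus vocabulary
    is smaller than requested.
    """
    vocab = build_vocabulary(corpus, R, C)
    cooc = log_transform(build_cooccurrence(corpus, vocab, pairs=pairs))
    d_eff = min(d, *cooc.values.shape)
    if d_eff < d:
        warnings.warn(
            f"requested d={d} exceeds matrix rank bound; using d={d_eff}",
            stacklevel=2,
        )
    return svd_compress(cooc, d_eff, word_vectors=word_vectors)
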