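"""Statement representations: unit-norm sums of word vectors.

A statement's semantic representation is the sum, dimension by
dimension, of the vectors of all its in-vocabulary tokens (repeated
words contribute repeatedly), renormalised to unit length.  Tokens
absent from the space (OOV) are skipped and counted.  No stop words are
removed: high-frequency function words carry signal in the keyword
analysis and must survive embedding unchanged.

By construction the representation is a bag of words — invariant to
token order — and dot products between statement embeddings are cosine
similarities because every vector has unit norm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import StatementRecord, Tokenizer, default_tokenizer
from .errors import DegenerateDataError
from .semantic_space import SemanticSpace

__all__ = ["StatementEmbedding", "embed_statement", "embed_all", "write_embeddings"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatementEmbedding:
    """Embedding of one statement, with token bookkeeping.

    ``vector`` is None (and ``valid`` False) when every token was OOV
    or the summed vector had zero norm; the caller decides whether to
    drop or fail.
    """

    statement_id: str
    vector: np.ndarray | None
    n_tokens_used: int
    n_tokens_oov: int

    @property
    def valid(self) -> bool:
        return self.vector is not None


def embed_statement(
    statement: StatementRecord,
    space: SemanticSpace,
    tokenizer: Tokenizer | None = None,
) -> StatementEmbedding:
    """Sum the space vectors of a statement's tokens and renormalise."""
    tokens = (tokenizer or default_tokenizer)(statement.text)
    total = np.zeros(space.d)
    used = oov = 0
    for tok in tokens:
        vec = space.get(tok)
        if vec is None:
            oov += 1
        else:
            total += vec
            used += 1
    norm = float(np.linalg.norm(total))
    if used == 0 or norm == 0.0:
        return StatementEmbedding(statement.statement_id, None, used, oov)
    return StatementEmbedding(statement.statement_id, total / norm, used, oov)


def embed_all(
    statements: Sequence[StatementRecord],
    space: SemanticSpace,
    tokenizer: Tokenizer | None = None,
) -> tuple[np.ndarray, np.ndarray, list[StatementEmbedding]]:
    """Embed a batch of statements into an (N x d) matrix.

    Returns the matrix (rows in input order; invalid rows are zero), a
    boolean validity mask, and the per-statement embeddings.  Raises
    :class:`DegenerateDataError` when no statement embeds validly.
    """
    if not statements:
        raise DegenerateDataError("no statements to embed")
    embeddings = [embed_statement(s, space, tokenizer) for s in statements]
    matrix = np.zeros((len(statements), space.d))
    mask = np.zeros(len(statements), dtype=bool)
    for i, emb in enumerate(embeddings):
        if emb.valid:
            matrix[i] = emb.vector
            mask[i] = True
    if not mask.any():
        raise DegenerateDataError("every statement was fully out-of-vocabulary")
    n_tokens = sum(e.n_tokens_used + e.n_tokens_oov for e in embeddings)
    n_oov = sum(e.n_tokens_oov for e in embeddings)
    logger.info(
        "embedded %d/%d statements (token OOV rate %.1f%%)",
        int(mask.sum()),
        len(statements),
        100.0 * n_oov / max(n_tokens, 1),
    )
    if not mask.all():
        invalid = [e.statement_id for e in embeddings if not e.valid]
        logger.warning(
            "dropping %d all-OOV statements (first few: %s)",
            len(invalid),
            invalid[:5],
        )
    return matrix, mask, embeddings


def write_embeddings(
    embeddings: Iterable[StatementEmbedding], path: str | Path
) -> None:
    """Export embeddings in the space TSV dialect, keyed by statement id."""
    path = Path(path)
    embeddings = list(embeddings)
    d = next((e.vector.shape[0] for e in embeddings if e.valid), 0)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#d={d}\n")
        for emb in embeddings:
            if emb.valid:
                fh.write(
                    emb.statement_id
                    + "\t"
                    + "\t".join(repr(float(v)) for v in emb.vector)
                    + "\n"
                )
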