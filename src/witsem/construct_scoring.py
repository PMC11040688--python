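"""Scoring statements against psychological construct representations.

Two routes, mirroring how constructs are operationalised:

* **word-list constructs** (communion, tentativeness): the construct is
  represented by the unit-norm sum of the vectors of its list words in
  a semantic space, and a statement's score is the dot product between
  its embedding and the construct vector — a cosine in [-1, +1];
* **rated constructs** (dominance, valence, abstractness): a regression
  model is trained to predict human word ratings from word embeddings
  (SVD-preprocessed, dimension count selected by cross-validation on
  ten random leave-out folds, no z-transform of the target), and the
  fitted model is applied to statement vectors.  Model outputs are raw
  regression predictions and are deliberately not clipped to the rating
  scale.

Statements may be scored in a different space than the one used for
accuracy prediction (e.g. an English space over translated text);
scoring only assumes the statement vectors and the construct live in
the same space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy_model import (
    DEFAULT_DIMENSION_GRID,
    _capped_grid,
    _ols_fit,
    _ols_predict,
    _select_k,
    nested_cv_predict,
    svd_preprocess,
    truncate_grid,
)
from .corpus_io import ConstructWordList, RatingList
from .errors import DegenerateDataError
from .semantic_space import SemanticSpace

__all__ = [
    "ConstructRepresentation",
    "RatingModel",
    "build_construct_representation",
    "similarity_score",
    "train_rating_model",
    "apply_rating_model",
    "score_statements_against_constructs",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Word-list constructs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstructRepresentation:
    """Unit-norm construct vector built from a word list."""

    name: str
    vector: np.ndarray
    n_words_used: int
    n_words_oov: int

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.vector))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"construct vector must be unit-norm (got {norm})")
        if self.n_words_used < 1:
            raise ValueError("construct must use at least one word")


def build_construct_representation(
    word_list: ConstructWordList,
    space: SemanticSpace,
) -> ConstructRepresentation:
    """Sum the list words' vectors and renormalise to unit length.

    Out-of-vocabulary list words are skipped and counted.  Zero
    in-vocabulary words, or a zero-norm sum (antipodal vectors), raise
    :class:`DegenerateDataError`.
    """
    total = np.zeros(space.d)
    used = oov = 0
    for word in word_list.words:
        vec = space.get(word)
        if vec is None:
            oov += 1
        else:
            total += vec
            used += 1
    if used == 0:
        raise DegenerateDataError(
            f"no word of construct list {word_list.name!r} is in the space"
        )
    norm = float(np.linalg.norm(total))
    if norm == 0.0:
        raise DegenerateDataError(
            f"construct list {word_list.name!r} sums to the zero vector"
        )
    if oov:
        logger.info("construct %s: %d/%d list words OOV", word_list.name, oov, used + oov)
    return ConstructRepresentation(
        name=word_list.name,
        vector=total / norm,
        n_words_used=used,
        n_words_oov=oov,
    )


def similarity_score(statement_vec: np.ndarray, construct_vec: np.ndarray) -> float:
    """Dot product of two unit vectors: the cosine similarity in [-1, 1]."""
    statement_vec = np.asarray(statement_vec)
    construct_vec = np.asarray(construct_vec)
    if statement_vec.shape != construct_vec.shape:
        raise ValueError(
            f"dimension mismatch: {statement_vec.shape} vs {construct_vec.shape}"
        )
    return float(statement_vec @ construct_vec)


# ---------------------------------------------------------------------------
# Rating-prediction models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingModel:
    """Regression from word-embedding SVD scores to construct ratings.

    ``basis`` (d x r) projects a vector from the space into the word
    SVD component basis; the model uses the first ``k`` components with
    ``coefficients`` = [intercept, b_1, ..., b_k].  ``cv_r`` is the
    Pearson correlation between out-of-fold predictions and ratings
    from the ten-fold leave-out procedure.
    """

    name: str
    basis: np.ndarray
    coefficients: np.ndarray
    k: int
    cv_r: float
    cv_p: float
    scale: tuple[float, float]
    n_words: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not -1.0 <= self.cv_r <= 1.0:
            raise ValueError(f"cv_r out of [-1, 1]: {self.cv_r}")


def train_rating_model(
    ratings: RatingList,
    space: SemanticSpace,
    grid: Sequence[int] = DEFAULT_DIMENSION_GRID,
    seed: int = 0,
    n_folds: int = 10,
    min_words: int = 20,
) -> RatingModel:
    """Fit a cross-validated rating predictor on the rated words in a space.

    Rated words found in the space are embedded and SVD-preprocessed;
    out-of-fold predictions come from the same nested dimension-selection
    regression as the accuracy model, except the target is the raw
    rating (no z-transform) and folds are ``n_folds`` random partitions
    under ``seed`` (word lists carry no theme structure).  The
    deployable model's dimension count is then selected by plain
    cross-validation over the same folds on all rated words and refit
    on all of them.
    """
    words = [w for w in ratings.entries if w in space]
    if len(words) < min_words:
        raise DegenerateDataError(
            f"only {len(words)} rated words present in the space "
            f"(need >= {min_words})"
        )
    y = np.array([ratings.entries[w] for w in words], dtype=np.float64)
    if np.all(y == y[0]):
        raise DegenerateDataError("constant ratings: correlation undefined")
    X = np.vstack([space.vector(w) for w in words])
    svd = svd_preprocess(X)
    n = len(words)
    rng = np.random.default_rng(seed)
    fold_codes = np.empty(n, dtype=int)
    fold_codes[rng.permutation(n)] = np.arange(n) % n_folds

    oof = nested_cv_predict(svd.scores, y, fold_codes, grid)
    cv_r, cv_p = stats.pearsonr(oof.predictions, y)

    # final model: plain CV over the same folds on all words
    candidates = _capped_grid(truncate_grid(grid, svd.scores.shape[1]), n, svd.scores.shape[1])
    mse = {}
    for k in candidates:
        sq = 0.0
        for g in np.unique(fold_codes):
            val = fold_codes == g
            beta = _ols_fit(svd.scores[~val][:, :k], y[~val])
            resid = y[val] - _ols_predict(beta, svd.scores[val][:, :k])
            sq += float(resid @ resid)
        mse[k] = sq / n
    best_k = _select_k(candidates, mse)
    beta = _ols_fit(svd.scores[:, :best_k], y)
    logger.info(
        "rating model %s: %d words, k=%d, cv_r=%.3f (p=%.2g)",
        ratings.name, n, best_k, cv_r, cv_p,
    )
    return RatingModel(
        name=ratings.name,
        basis=svd.basis,
        coefficients=beta,
        k=best_k,
        cv_r=float(cv_r),
        cv_p=float(cv_p),
        scale=(ratings.scale_min, ratings.scale_max),
        n_words=n,
    )


def apply_rating_model(model: RatingModel, statement_vec: np.ndarray) -> float:
    """Predicted rating for a vector in the model's space geometry.

    The vector is projected into the word-SVD basis and fed through the
    linear model; outputs are not clipped to the rating scale.
    """
    statement_vec = np.asarray(statement_vec, dtype=np.float64)
    if statement_vec.shape != (model.basis.shape[0],):
        raise ValueError(
            f"vector dimension {statement_vec.shape} does not match model "
            f"space dimension {model.basis.shape[0]}"
        )
    scores = statement_vec @ model.basis
    return float(model.coefficients[0] + model.coefficients[1:] @ scores[: model.k])


# ---------------------------------------------------------------------------
# Batch scoring
# ---------------------------------------------------------------------------


def score_statements_against_constructs(
    statement_ids: Sequence[str],
    embedding_matrix: np.ndarray,
    valid_mask: np.ndarray,
    constructs: Sequence[ConstructRepresentation] = (),
    models: Sequence[RatingModel] = (),
) -> pd.DataFrame:
    """Score table: one row per statement, one column per construct.

    Word-list constructs yield cosine scores; rating models yield raw
    predicted ratings.  Rows whose embedding is invalid get NaN.
    """
    if not constructs and not models:
        raise ValueError("need at least one construct or rating model")
    valid_mask = np.asarray(valid_mask, dtype=bool)
    table: dict[str, np.ndarray] = {}
    for rep in constructs:
        col = embedding_matrix @ rep.vector
        col = np.where(valid_mask, col, np.nan)
        table[rep.name] = col
    for model in models:
        proj = embedding_matrix @ model.basis[:, : model.k]
        col = model.coefficients[0] + proj @ model.coefficients[1:]
        col = np.where(valid_mask, col, np.nan)
        table[model.name] = col
    return pd.DataFrame(table, index=pd.Index(statement_ids, name="statement_id"))
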