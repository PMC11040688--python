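"""Accuracy prediction from statement embeddings via nested cross-validation.

The procedure:

1. statements are partitioned into K folds by their topical *theme*
   (K = 11 in the full design), so that train and test statements never
   share a topic;
2. the binary accuracy labels are z-transformed *within each fold*
   (sample sd, ddof = 1), which removes between-theme base-rate
   differences the regression could otherwise exploit, and turns the
   problem into regression rather than classification;
3. the statement-embedding matrix is itself SVD-decomposed and each
   statement is represented by its component scores in
   decreasing-singular-value order;
4. for each outer fold, an inner leave-one-fold-out loop over the
   remaining K-1 folds selects the number of leading components k* from
   a fixed grid (by inner out-of-fold mean squared error, ties going to
   the smaller k), an ordinary least-squares regression with intercept
   on the first k* components is fit on all non-test data, and
   predictions are emitted for the held-out fold — so every statement
   receives exactly one out-of-fold prediction and each fold may use a
   different k*;
5. predicted scores are compared between correct and incorrect
   statements with a pooled two-sample t-test and Cohen's d, plus the
   mean squared error of the predictions against the z-scale labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import StatementRecord
from .errors import DegenerateDataError
from .group_stats import GroupComparison, two_group_test
from .semantic_space import fix_svd_signs

__all__ = [
    "DEFAULT_DIMENSION_GRID",
    "FoldPlan",
    "AccuracyPredictions",
    "truncate_grid",
    "make_theme_folds",
    "z_transform_per_fold",
    "svd_preprocess",
    "SVDScores",
    "nested_cv_predict",
    "compare_predicted",
    "run_accuracy_model",
]

logger = logging.getLogger(__name__)

#: Candidate numbers of leading SVD components tried during selection.
#: Roughly geometric, from a single component up to 768; entries above
#: the available dimensionality are dropped at run time.
DEFAULT_DIMENSION_GRID: tuple[int, ...] = (
    1, 2, 3, 5, 7, 10, 14, 19, 26, 35, 46, 61, 80,
    105, 137, 179, 234, 305, 397, 488, 768,
)


def truncate_grid(grid: Sequence[int], max_dim: int) -> tuple[int, ...]:
    """Validate a dimension grid and truncate it at ``max_dim``."""
    grid = tuple(int(k) for k in grid)
    if not grid:
        raise ValueError("dimension grid is empty")
    if any(k < 1 for k in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError(f"grid must be strictly increasing positive integers: {grid}")
    if max_dim < 1:
        raise ValueError(f"max_dim must be >= 1, got {max_dim}")
    kept = tuple(k for k in grid if k <= max_dim)
    return kept if kept else (max_dim,)


# ---------------------------------------------------------------------------
# Theme folds and per-fold z-transform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """Partition of statements into theme-defined folds.

    ``themes`` fixes the fold order (sorted theme labels);
    ``assignment`` maps statement id -> theme.
    """

    themes: tuple[str, ...]
    assignment: Mapping[str, str]

    @property
    def n_folds(self) -> int:
        return len(self.themes)

    def fold_codes(self, statement_ids: Sequence[str]) -> np.ndarray:
        """Integer fold index (position in ``themes``) per statement id."""
        theme_idx = {t: i for i, t in enumerate(self.themes)}
        return np.array(
            [theme_idx[self.assignment[sid]] for sid in statement_ids], dtype=int
        )


def make_theme_folds(
    statements: Sequence[StatementRecord],
    require_both_classes: bool = True,
) -> FoldPlan:
    """One fold per theme; every theme must contain both accuracy classes.

    The per-fold z-transform is undefined for a single-class fold, so
    such a theme raises :class:`DegenerateDataError` naming the theme
    (disable via ``require_both_classes`` for label-free uses).
    """
    by_theme: dict[str, list[StatementRecord]] = {}
    for s in statements:
        by_theme.setdefault(s.theme, []).append(s)
    for theme, members in sorted(by_theme.items()):
        if len(members) < 2:
            raise DegenerateDataError(
                f"theme {theme!r} has only {len(members)} statement(s); "
                "folds need at least 2"
            )
        if require_both_classes and len({s.accuracy for s in members}) < 2:
            raise DegenerateDataError(
                f"theme {theme!r} contains a single accuracy class; "
                "the per-fold z-transform is undefined"
            )
    return FoldPlan(
        themes=tuple(sorted(by_theme)),
        assignment={s.statement_id: s.theme for s in statements},
    )


def z_transform_per_fold(
    labels: np.ndarray,
    fold_codes: np.ndarray,
    return_params: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict[int, tuple[float, float]]]:
    """Standardise labels within each fold (sample sd, ddof = 1).

    Within every fold the output has mean 0 and sd 1, which removes
    fold-level base-rate information from the target.  A fold with zero
    variance raises :class:`DegenerateDataError`.
    """
    labels = np.asarray(labels, dtype=np.float64)
    z = np.empty_like(labels)
    params: dict[int, tuple[float, float]] = {}
    for f in np.unique(fold_codes):
        sel = fold_codes == f
        mean = float(labels[sel].mean())
        sd = float(labels[sel].std(ddof=1))
        if sd == 0.0:
            raise DegenerateDataError(
                f"fold {int(f)} has zero label variance; z-transform undefined"
            )
        z[sel] = (labels[sel] - mean) / sd
        params[int(f)] = (mean, sd)
    return (z, params) if return_params else z


# ---------------------------------------------------------------------------
# SVD preprocessing of the embedding matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SVDScores:
    """Statement component scores plus the basis that produced them.

    ``scores`` = U S (N x r, decreasing singular values, deterministic
    signs); ``basis`` = V (d x r), so a new vector v in the original
    space projects to ``v @ basis``.
    """

    scores: np.ndarray
    basis: np.ndarray
    singular_values: np.ndarray


def svd_preprocess(embeddings: np.ndarray) -> SVDScores:
    """SVD-decompose an (N x d) embedding matrix into component scores.

    Components beyond the numerical rank are discarded with a warning;
    the score matrix has at most min(N, d) columns.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 embeddings to SVD-preprocess")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, Vt = fix_svd_signs(U, Vt)
    tol = S[0] * max(X.shape) * np.finfo(np.float64).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    if rank < S.size:
        warnings.warn(
            f"embedding matrix is rank-deficient (rank {rank} < {S.size}); "
            "truncating component scores",
            stacklevel=2,
        )
    return SVDScores(
        scores=U[:, :rank] * S[:rank],
        basis=Vt[:rank].T,
        singular_values=S[:rank],
    )


# ---------------------------------------------------------------------------
# Nested cross-validated regression
# ---------------------------------------------------------------------------


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with intercept; returns [intercept, coef_1, ..., coef_k]."""
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _ols_predict(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return beta[0] + X @ beta[1:]


@dataclass(frozen=True)
class AccuracyPredictions:
    """Out-of-fold predictions and per-fold selection bookkeeping.

    ``predictions`` is aligned with the rows passed to
    :func:`nested_cv_predict` (z-scale); ``chosen_dims`` and
    ``coefficients`` (intercept first) are keyed by fold code;
    ``z_params`` holds each fold's (mean, sd) used to standardise the
    binary labels, when supplied by the orchestrator.
    """

    predictions: np.ndarray
    chosen_dims: Mapping[int, int]
    coefficients: Mapping[int, np.ndarray]
    inner_mse: Mapping[int, Mapping[int, float]] = field(default_factory=dict)
    z_params: Mapping[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def mean_dims(self) -> float:
        """Mean selected dimension count over folds."""
        return float(np.mean(list(self.chosen_dims.values())))

    @property
    def sd_dims(self) -> float:
        values = list(self.chosen_dims.values())
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def _capped_grid(grid: Sequence[int], n_train: int, n_cols: int) -> list[int]:
    """Grid entries usable with ``n_train`` samples (k <= n_train - 2)."""
    cap = min(n_train - 2, n_cols)
    kept = [k for k in grid if k <= cap]
    if len(kept) < len(grid):
        warnings.warn(
            f"dimension grid capped at {cap} (training size {n_train})",
            stacklevel=3,
        )
    return kept if kept else [max(1, cap)]


def _select_k(candidates: Sequence[int], mse: Mapping[int, float]) -> int:
    """Smallest k whose CV error is not beaten by a *meaningful* margin.

    A larger k wins only if it improves the MSE beyond numerical noise
    (relative 1e-9, absolute 1e-12); exact-fit ties therefore resolve
    to the most parsimonious model.
    """
    best = candidates[0]
    for k in candidates[1:]:
        if mse[k] < mse[best] - max(1e-12, 1e-9 * mse[best]):
            best = k
    return best


def nested_cv_predict(
    scores: np.ndarray,
    z_labels: np.ndarray,
    fold_codes: np.ndarray,
    grid: Sequence[int] = DEFAULT_DIMENSION_GRID,
) -> AccuracyPredictions:
    """Out-of-fold regression predictions with nested dimension selection.

    For each outer fold, the inner loop leaves out one of the remaining
    folds at a time, computes the out-of-fold MSE for every candidate k
    in the grid, and picks the k with the smallest inner MSE (smallest k
    on ties).  The final model for that fold is OLS on all non-test
    data using the first k* component scores.  Test labels are never
    touched during selection or fitting.
    """
    scores = np.asarray(scores, dtype=np.float64)
    z_labels = np.asarray(z_labels, dtype=np.float64)
    fold_codes = np.asarray(fold_codes, dtype=int)
    if not (len(scores) == len(z_labels) == len(fold_codes)):
        raise ValueError("scores, labels and fold codes must be aligned")
    folds = np.unique(fold_codes)
    if folds.size < 2:
        raise DegenerateDataError("nested CV needs at least 2 folds")
    grid = truncate_grid(grid, scores.shape[1])

    predictions = np.full(len(z_labels), np.nan)
    chosen: dict[int, int] = {}
    coefs: dict[int, np.ndarray] = {}
    inner_mse_all: dict[int, dict[int, float]] = {}

    for f in folds:
        test = fold_codes == f
        train = ~test
        inner_folds = [g for g in folds if g != f]
        candidates = _capped_grid(grid, int(train.sum()), scores.shape[1])

        sq_err = {k: 0.0 for k in candidates}
        n_inner = 0
        for g in inner_folds:
            val = fold_codes == g
            fit = train & ~val
            n_fit = int(fit.sum())
            n_inner += int(val.sum())
            for k in candidates:
                kk = min(k, max(1, n_fit - 2))
                beta = _ols_fit(scores[fit][:, :kk], z_labels[fit])
                resid = z_labels[val] - _ols_predict(beta, scores[val][:, :kk])
                sq_err[k] += float(resid @ resid)
        inner_mse = {k: sq_err[k] / n_inner for k in candidates}
        best_k = _select_k(candidates, inner_mse)

        beta = _ols_fit(scores[train][:, :best_k], z_labels[train])
        predictions[test] = _ols_predict(beta, scores[test][:, :best_k])
        chosen[int(f)] = best_k
        coefs[int(f)] = beta
        inner_mse_all[int(f)] = inner_mse
        logger.debug("fold %d: k*=%d (inner MSE %.4f)", f, best_k, inner_mse[best_k])

    return AccuracyPredictions(
        predictions=predictions,
        chosen_dims=chosen,
        coefficients=coefs,
        inner_mse=inner_mse_all,
    )


# ---------------------------------------------------------------------------
# Group comparison of predicted scores
# ---------------------------------------------------------------------------


def compare_predicted(
    predictions: np.ndarray,
    labels: np.ndarray,
    z_labels: np.ndarray | None = None,
    measure: str = "Accuracy (LSA)",
    language: str = "",
) -> GroupComparison:
    """t-test of predicted scores between incorrect and correct statements.

    Pooled two-sample t with df = N - 2; Cohen's d is
    (mean_incorrect - mean_correct) / pooled sd, so a negative d means
    correct statements received higher predicted scores.  When
    ``z_labels`` is given, the comparison also carries the mean squared
    error between predictions and the z-scale labels.
    """
    mse = None
    if z_labels is not None:
        resid = np.asarray(predictions) - np.asarray(z_labels)
        mse = float(np.mean(resid**2))
    return two_group_test(
        np.asarray(predictions),
        np.asarray(labels),
        measure=measure,
        language=language,
        mse=mse,
    )


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------


def run_accuracy_model(
    statements: Sequence[StatementRecord],
    embedding_matrix: np.ndarray,
    valid_mask: np.ndarray | None = None,
    grid: Sequence[int] = DEFAULT_DIMENSION_GRID,
    measure: str = "Accuracy (LSA)",
    language: str = "",
) -> tuple[AccuracyPredictions, GroupComparison, np.ndarray]:
    """Full accuracy-model pass on embedded statements.

    Masks invalid embeddings, builds theme folds, z-transforms labels
    per fold, SVD-preprocesses embeddings, runs nested CV, and compares
    predicted scores between classes.  Returns the predictions (aligned
    with the *valid* statements), the group comparison, and the valid
    row indices into ``statements``.
    """
    statements = list(statements)
    if valid_mask is None:
        valid_mask = np.ones(len(statements), dtype=bool)
    idx = np.flatnonzero(valid_mask)
    kept = [statements[i] for i in idx]
    if len(kept) < 4:
        raise DegenerateDataError("too few valid statements for accuracy modelling")
    plan = make_theme_folds(kept)
    ids = [s.statement_id for s in kept]
    fold_codes = plan.fold_codes(ids)
    labels = np.array([s.accuracy for s in kept], dtype=np.float64)
    z, z_params = z_transform_per_fold(labels, fold_codes, return_params=True)
    svd = svd_preprocess(embedding_matrix[idx])
    result = nested_cv_predict(svd.scores, z, fold_codes, grid)
    result = AccuracyPredictions(
        predictions=result.predictions,
        chosen_dims=result.chosen_dims,
        coefficients=result.coefficients,
        inner_mse=result.inner_mse,
        z_params=z_params,
    )
    comparison = compare_predicted(
        result.predictions, labels, z, measure=measure, language=language
    )
    logger.info(
        "%s: mean dims %.1f (sd %.1f), t=%.2f, d=%.2f, MSE=%.2f",
        measure,
        result.mean_dims,
        result.sd_dims,
        comparison.t,
        comparison.cohens_d,
        comparison.mse if comparison.mse is not None else float("nan"),
    )
    return result, comparison, idx
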