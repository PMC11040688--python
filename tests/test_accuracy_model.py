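"""Theme folds, per-fold z-transform, and nested-CV accuracy prediction."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from witsem import (
    DegenerateDataError,
    SimulationConfig,
    StatementRecord,
    build_space,
    compare_predicted,
    embed_all,
    make_theme_folds,
    nested_cv_predict,
    run_accuracy_model,
    simulate_corpus,
    simulate_statements,
    svd_preprocess,
    z_transform_per_fold,
)
from witsem.accuracy_model import DEFAULT_DIMENSION_GRID, truncate_grid


def _stmts(themes_accs):
    return [
        StatementRecord(f"s{i}", f"text {i}", theme, acc)
        for i, (theme, acc) in enumerate(themes_accs)
    ]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def test_theme_folds_partition(bundle):
    plan = make_theme_folds(bundle.statements)
    codes = plan.fold_codes([s.statement_id for s in bundle.statements])
    assert plan.n_folds == 11
    sizes = np.bincount(codes, minlength=plan.n_folds)
    assert sizes.sum() == len(bundle.statements)
    assert (sizes >= 2).all()


def test_two_theme_partition():
    plan = make_theme_folds(
        _stmts([("a", 0), ("a", 1), ("a", 1), ("b", 0), ("b", 1), ("b", 1)])
    )
    assert plan.themes == ("a", "b")


def test_single_class_theme_is_named():
    with pytest.raises(DegenerateDataError, match="'allcorrect'"):
        make_theme_folds(
            _stmts(
                [("allcorrect", 1), ("allcorrect", 1), ("mixed", 0), ("mixed", 1)]
            )
        )


# ---------------------------------------------------------------------------
# z-transform
# ---------------------------------------------------------------------------


def test_z_transform_hand_example():
    z = z_transform_per_fold(np.array([1, 1, 0, 0]), np.zeros(4, dtype=int))
    np.testing.assert_allclose(z, [0.8660254, 0.8660254, -0.8660254, -0.8660254])


@pytest.mark.parametrize("labels", [[1, 1, 0], [1, 0, 0, 1, 1, 0, 1]])
def test_z_transform_moments(labels):
    z = z_transform_per_fold(np.array(labels), np.zeros(len(labels), dtype=int))
    assert abs(z.mean()) < 1e-12
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_z_transform_degenerate_fold():
    with pytest.raises(DegenerateDataError):
        z_transform_per_fold(np.array([1, 1, 1]), np.zeros(3, dtype=int))


def test_z_transform_is_per_fold():
    labels = np.array([1, 1, 0, 1, 0, 0])
    codes = np.array([0, 0, 0, 1, 1, 1])
    z = z_transform_per_fold(labels, codes)
    for f in (0, 1):
        assert abs(z[codes == f].mean()) < 1e-12
        assert z[codes == f].std(ddof=1) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# SVD preprocessing
# ---------------------------------------------------------------------------


def test_svd_preprocess_oracle_and_rank_bound():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(5, 3))
    svd = svd_preprocess(X)
    assert svd.scores.shape[1] <= min(X.shape)
    # scores @ basis.T reconstructs X (full rank here)
    np.testing.assert_allclose(svd.scores @ svd.basis.T, X, atol=1e-10)
    # pairwise distances preserved (scores are a rotation of X)
    from scipy.spatial.distance import pdist

    np.testing.assert_allclose(pdist(svd.scores), pdist(X), atol=1e-10)


def test_svd_preprocess_duplicate_rows_identical_scores():
    rng = np.random.default_rng(1)
    row = rng.normal(size=4)
    X = np.vstack([row, rng.normal(size=4), row])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svd = svd_preprocess(X)
    np.testing.assert_allclose(svd.scores[0], svd.scores[2], atol=1e-12)


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------


def test_grid_truncation():
    assert truncate_grid(DEFAULT_DIMENSION_GRID, 300)[-1] == 234
    assert truncate_grid((1, 2, 3), 2) == (1, 2)
    assert truncate_grid((5, 10), 3) == (3,)
    with pytest.raises(ValueError):
        truncate_grid((3, 2), 10)


def _planted_linear(n=120, n_folds=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n, 8)) * (10.0 ** -np.arange(8))
    z = 1.5 * scores[:, 0] + noise * rng.normal(size=n)
    codes = np.arange(n) % n_folds
    return scores, z, codes


def test_planted_linear_signal_selects_one_dimension():
    scores, z, codes = _planted_linear()
    result = nested_cv_predict(scores, z, codes, grid=(1, 2, 3, 5))
    assert set(result.chosen_dims.values()) == {1}
    assert np.corrcoef(result.predictions, z)[0, 1] > 0.999


def test_every_statement_predicted_once_and_k_in_grid():
    scores, z, codes = _planted_linear(noise=1.0)
    grid = (1, 2, 3, 5)
    result = nested_cv_predict(scores, z, codes, grid=grid)
    assert not np.isnan(result.predictions).any()
    assert set(result.chosen_dims) == set(range(6))
    assert all(k in grid for k in result.chosen_dims.values())


def test_permutation_null_gives_no_effect():
    """Shuffled labels: mean |d| of predicted scores stays near zero."""
    rng = np.random.default_rng(42)
    n, n_folds = 220, 11
    ds = []
    for _ in range(20):
        scores = rng.normal(size=(n, 12))
        labels = rng.random(n) < 0.75
        codes = np.arange(n) % n_folds
        # guarantee both classes per fold
        for f in range(n_folds):
            idx = np.flatnonzero(codes == f)
            labels[idx[0]] = False
            labels[idx[1]] = True
        z = z_transform_per_fold(labels.astype(float), codes)
        result = nested_cv_predict(scores, z, codes, grid=(1, 2, 3, 5, 7, 10))
        cmp_ = compare_predicted(result.predictions, labels.astype(int), z)
        ds.append(cmp_.cohens_d)
    assert abs(np.mean(ds)) < 0.15


def test_base_rate_differences_alone_produce_no_effect():
    """Unequal theme base rates without semantic signal: |mean d| < 0.15.

    This is the stated purpose of the per-fold z-transform — the model
    must not be able to learn theme-level accuracy differences.
    """
    ds = []
    for seed in range(6):
        cfg = SimulationConfig(
            seed=200 + seed, delta=0.0, n_statements=600, n_grams=8_000,
            base_accuracy=0.75, accuracy_spread=0.10,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corpus, _ = simulate_corpus(cfg)
            space = build_space(corpus, R=240, C=240, d=60)
            stmts = simulate_statements(cfg)
            matrix, mask, _ = embed_all(stmts, space)
            _, cmp_, _ = run_accuracy_model(
                stmts, matrix, mask, grid=(1, 2, 3, 5, 7, 10, 14)
            )
        ds.append(cmp_.cohens_d)
    assert abs(np.mean(ds)) < 0.15


def test_leakage_guard_label_mutation():
    """Changing labels inside an outer test fold must not change that
    fold's selected dimension count or fitted coefficients."""
    rng = np.random.default_rng(3)
    n, n_folds = 120, 6
    scores = rng.normal(size=(n, 10))
    codes = np.arange(n) % n_folds
    labels = (rng.random(n) < 0.7).astype(float)
    for f in range(n_folds):
        idx = np.flatnonzero(codes == f)
        labels[idx[0]], labels[idx[1]] = 0.0, 1.0
    z = z_transform_per_fold(labels, codes)
    base = nested_cv_predict(scores, z, codes, grid=(1, 2, 3, 5))
    f = 2
    mutated = labels.copy()
    idx = np.flatnonzero(codes == f)
    mutated[idx[2:]] = 1.0 - mutated[idx[2:]]  # keep both classes present
    z_mut = z_transform_per_fold(mutated, codes)
    out = nested_cv_predict(scores, z_mut, codes, grid=(1, 2, 3, 5))
    assert out.chosen_dims[f] == base.chosen_dims[f]
    np.testing.assert_array_equal(out.coefficients[f], base.coefficients[f])


def test_sign_flip_invariance(bundle, space, embedded):
    """Flipping embedding dimensions (singular-vector signs) leaves the
    component scores, and hence all predictions, unchanged."""
    matrix, mask, _ = embedded
    flip = np.ones(space.d)
    flip[::2] = -1.0
    a = svd_preprocess(matrix[mask])
    b = svd_preprocess(matrix[mask] * flip)
    np.testing.assert_allclose(a.scores, b.scores, atol=1e-9)


# ---------------------------------------------------------------------------
# compare_predicted
# ---------------------------------------------------------------------------


def test_identical_groups_give_zero_effect():
    preds = np.array([0.3, 0.7, 0.3, 0.7])
    labels = np.array([0, 0, 1, 1])
    cmp_ = compare_predicted(preds, labels)
    assert cmp_.t == 0.0
    assert cmp_.cohens_d == 0.0


def test_hand_computed_t_and_d():
    preds = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    labels = np.array([0, 0, 0, 1, 1, 1])  # incorrect = [1,2,3], correct = [4,5,6]
    cmp_ = compare_predicted(preds, labels)
    assert cmp_.t == pytest.approx(-3.674, abs=1e-3)
    assert cmp_.cohens_d == pytest.approx(-3.0, abs=1e-12)
    assert cmp_.df == 4
    assert cmp_.p == pytest.approx(0.0214, abs=2e-4)


def test_perfect_predictions_have_zero_mse():
    labels = np.array([0, 1, 1, 0, 1, 1, 0])
    codes = np.array([0, 0, 0, 0, 1, 1, 1])  # unequal folds -> distinct z values
    z = z_transform_per_fold(labels.astype(float), codes)
    cmp_ = compare_predicted(z, labels, z)
    assert cmp_.mse == 0.0


def test_single_class_errors():
    with pytest.raises(DegenerateDataError):
        compare_predicted(np.array([1.0, 2.0]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# Orchestrated run on the shared bundle
# ---------------------------------------------------------------------------


def test_run_accuracy_model_end_to_end(bundle, embedded):
    matrix, mask, _ = embedded
    result, cmp_, idx = run_accuracy_model(bundle.statements, matrix, mask)
    assert len(result.predictions) == int(mask.sum())
    assert not np.isnan(result.predictions).any()
    assert set(result.chosen_dims.values()) <= set(DEFAULT_DIMENSION_GRID)
    assert cmp_.n == int(mask.sum())
    assert cmp_.mse is not None and cmp_.mse > 0
    # z bookkeeping recorded per fold
    assert len(result.z_params) == 11
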