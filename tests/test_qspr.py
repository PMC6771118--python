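import numpy as np
import pytest
import statsmodels.api as sm

import bestqspr as bq
from bestqspr.qspr import (
    QsprDataset,
    QsprRegressor,
    SingularFitError,
    fit_ols,
    fit_with_outlier_removal,
    flag_outliers,
    loo_residuals,
)
from conftest import brute_force_loo


def make_ds(x, y, ids=None):
    x = np.asarray(x, float)
    return QsprDataset(
        ids=ids or [f"p{i}" for i in range(len(x))], x=x, y=np.asarray(y, float),
        provenance="synthetic",
    )


# -- plain OLS ---------------------------------------------------------------


def test_reference_survivor_fit_matches_published_line(reference_dataset):
    keep = [i not in bq.REFERENCE_OUTLIERS for i in reference_dataset.ids]
    survivors = reference_dataset.subset(np.array(keep))
    m = fit_ols(survivors)
    assert m.slope == pytest.approx(0.24935, abs=1e-5)
    assert m.intercept == pytest.approx(6.56527, abs=1e-5)
    assert m.n_used == 15


def test_ols_agrees_with_statsmodels(reference_dataset):
    """Independent cross-check of the whole statistic set on the survivor fit."""
    keep = np.array([i not in bq.REFERENCE_OUTLIERS for i in reference_dataset.ids])
    survivors = reference_dataset.subset(keep)
    m = fit_ols(survivors)
    ref = sm.OLS(survivors.y, sm.add_constant(survivors.x)).fit()
    assert m.intercept == pytest.approx(ref.params[0], abs=1e-9)
    assert m.slope == pytest.approx(ref.params[1], abs=1e-9)
    assert m.r2 == pytest.approx(ref.rsquared, abs=1e-9)
    assert m.f_stat == pytest.approx(ref.fvalue, abs=1e-6)
    assert m.significant == (ref.f_pvalue < 0.05)


def test_two_points_interpolate_exactly():
    est = QsprRegressor(remove_outliers=False)
    with pytest.raises(SingularFitError):
        est.fit([1.0, 2.0], [3.0, 5.0])  # < 3 points refused at the estimator level
    m = fit_ols(make_ds([1, 2, 3], [3, 5, 7]))
    assert m.slope == pytest.approx(2.0) and m.intercept == pytest.approx(1.0)
    assert m.r2 == pytest.approx(1.0)


def test_noiseless_line_is_recovered_with_unit_r2():
    x = np.arange(10, dtype=float)
    m = fit_ols(make_ds(x, 2 * x + 1))
    assert m.slope == pytest.approx(2.0, abs=1e-12)
    assert m.intercept == pytest.approx(1.0, abs=1e-12)
    assert m.r2 == pytest.approx(1.0)
    assert m.f_stat == np.inf  # perfect fit sentinel


def test_degenerate_x_raises():
    with pytest.raises(SingularFitError):
        fit_ols(make_ds([5, 5, 5, 5], [1, 2, 3, 4]))


def test_residuals_sum_to_zero(reference_dataset):
    m = fit_ols(reference_dataset)
    resid = reference_dataset.y - m.predict(reference_dataset.x)
    assert abs(resid.sum()) < 1e-9 * np.abs(reference_dataset.y).sum()


# -- leave-one-out -----------------------------------------------------------


def test_loo_shortcut_equals_brute_force_on_random_datasets():
    """The leverage shortcut must match 50 sets of explicit drop-one refits."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(5, 15))
        x = rng.uniform(0, 100, n)
        y = np.clip(0.25 * x + 6.6 + rng.normal(0, 5, n), 0, 100)
        ds = make_ds(x, y)
        np.testing.assert_allclose(
            loo_residuals(ds), brute_force_loo(x, y), rtol=0, atol=1e-9
        )


def test_loo_residuals_zero_on_noiseless_line():
    x = np.arange(6, dtype=float)
    assert np.allclose(loo_residuals(make_ds(x, 3 * x + 2)), 0.0, atol=1e-10)


def test_displaced_point_has_largest_loo_residual():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = 2 * x + 1
    y[2] += 10.0
    loo = loo_residuals(make_ds(x, y))
    assert np.argmax(np.abs(loo)) == 2


# -- outlier flagging and removal -------------------------------------------


def test_flag_outliers_empty_on_noiseless_line():
    x = np.arange(8, dtype=float)
    assert flag_outliers(make_ds(x, 0.5 * x + 2)) == set()


def test_flag_outliers_finds_planted_gross_point():
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 100, 12)
    y = 0.25 * x + 6.6 + rng.normal(0, 1, 12)
    y[4] += 30.0  # 30 sigma offset
    assert flag_outliers(make_ds(x, y)) == {"p4"}


def test_first_pass_flags_subset_of_named_outliers(reference_dataset):
    first = flag_outliers(reference_dataset)
    assert first
    assert first <= bq.REFERENCE_OUTLIERS


def test_iterative_removal_reproduces_reference_endpoint(reference_fit):
    assert set(reference_fit.outlier_ids) == set(bq.REFERENCE_OUTLIERS)
    assert reference_fit.n_used == 15
    assert reference_fit.slope == pytest.approx(0.24935, abs=1e-5)


def test_removal_is_idempotent_on_survivors(reference_dataset, reference_fit):
    keep = np.array(
        [i not in set(reference_fit.outlier_ids) for i in reference_dataset.ids]
    )
    again = fit_with_outlier_removal(reference_dataset.subset(keep))
    assert again.outlier_ids == []
    assert again.slope == pytest.approx(reference_fit.slope, abs=1e-12)


def test_no_removal_on_noiseless_line():
    x = np.arange(10, dtype=float)
    m = fit_with_outlier_removal(make_ds(x, 2 * x + 1))
    assert m.outlier_ids == [] and m.n_used == 10


def test_refusal_when_too_few_survivors_possible():
    with pytest.raises(SingularFitError):
        fit_with_outlier_removal(make_ds([1, 2], [1, 2]))


def test_outlier_count_conservation(reference_dataset, reference_fit):
    assert reference_fit.n_used + len(reference_fit.outlier_ids) == len(
        reference_dataset
    )


# -- model statistics --------------------------------------------------------


def test_reference_statistics(reference_fit):
    r2, r2_xv, f, significant = bq.model_statistics(reference_fit)
    assert r2 == pytest.approx(0.854, abs=5e-4)
    assert f == pytest.approx(76.164, abs=5e-3)
    assert significant
    # PRESS-based predicted R^2; the original software's exact formula is
    # unpublished, so this value carries a wider band than R^2
    assert r2_xv == pytest.approx(0.809, abs=5e-3)


def test_f_stat_identity(reference_fit):
    m = reference_fit
    assert m.f_stat == pytest.approx(m.r2 / (1 - m.r2) * (m.n_used - 2), rel=1e-12)


# -- estimator API -----------------------------------------------------------


def test_sklearn_contract():
    from sklearn.base import clone

    est = QsprRegressor(ddof=0, q2_adequate=0.6)
    cloned = clone(est)
    assert cloned.get_params()["ddof"] == 0
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 100, 20)
    y = 0.25 * x + 6.6 + rng.normal(0, 3, 20)
    est.fit(x[:, None], y)
    assert est.coef_.shape == (1,)
    pred = est.predict(np.array([[0.0], [10.0]]))
    assert pred[1] - pred[0] == pytest.approx(10 * est.slope_)
    assert est.score(x[:, None], y) > 0.5  # RegressorMixin R^2


def test_parameter_recovery_within_band():
    """Slope recovered within +/-0.05 of truth in >=95% of replicates
    (sigma=3, n=20, no outliers)."""
    rng = np.random.default_rng(2024)
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        x = rng.uniform(0, 100, 20)
        y = np.clip(0.24935 * x + 6.56527 + rng.normal(0, 3, 20), 0, 100)
        m = fit_with_outlier_removal(make_ds(x, y))
        hits += abs(m.slope - 0.24935) <= 0.05
    assert hits / n_rep >= 0.95
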