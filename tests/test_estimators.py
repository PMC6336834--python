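"""Sample item-assessment methods against direct-formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import itemselect as its
from itemselect.estimators import (
    PopulationScores,
    ScoreMatrix,
    SingularCovarianceError,
    UndefinedValueError,
    _StatsView,
)
from conftest import random_binary_matrix


# -- independent oracles -----------------------------------------------------


def oracle_citc(x, i):
    rest = x.sum(axis=1) - x[:, i]
    return np.corrcoef(x[:, i], rest)[0, 1]


def oracle_alpha(x):
    s = np.cov(x.T, ddof=1)
    return x.shape[1] / (x.shape[1] - 1) * (1 - np.trace(s) / s.sum())


def oracle_lambda6(x, i):
    """Residual variance via explicit normal-equations regression."""
    others = [j for j in range(x.shape[1]) if j != i]
    a = np.hstack([x[:, others], np.ones((len(x), 1))])
    coef, *_ = np.linalg.lstsq(a, x[:, i], rcond=None)
    resid = x[:, i] - a @ coef
    eps2 = resid @ resid / (len(x) - 1)
    return 1 - eps2 / np.var(x[:, i], ddof=1)


# -- ScoreMatrix container ---------------------------------------------------


def test_score_matrix_validation():
    with pytest.raises(ValueError):
        ScoreMatrix(np.array([[0, 2], [1, 0]]))
    with pytest.raises(ValueError):
        ScoreMatrix(np.zeros((2, 2)), item_labels=[1, 1])
    sm = ScoreMatrix(np.array([[0, 1], [1, 0]]), item_labels=[5, 9])
    assert sm.N == 2 and sm.J == 2
    assert sm.position(9) == 1


def test_score_matrix_subset_shares_statistics(f1):
    f1.cov(), f1.joint()  # populate caches
    sub = f1.subset([3, 1])
    assert list(sub.item_labels) == [3, 1]
    np.testing.assert_allclose(sub.cov(), np.cov(f1.values[:, [2, 0]].T, ddof=1))
    np.testing.assert_allclose(sub.popularity(), [3 / 8, 7 / 8])


def test_score_matrix_csv_roundtrip(tmp_path, f2):
    plain = tmp_path / "scores.csv"
    f2.to_csv(plain)
    assert plain.read_text().splitlines()[0] == "0,0,0"
    back = ScoreMatrix.from_csv(plain)
    np.testing.assert_array_equal(back.values, f2.values)
    with_header = tmp_path / "scores_h.csv"
    sm = ScoreMatrix(f2.values, item_labels=[10, 20, 30])
    sm.to_csv(with_header, header=True)
    back = ScoreMatrix.from_csv(with_header)
    assert list(back.item_labels) == [10, 20, 30]


# -- CITC and coefficient alpha ----------------------------------------------


def test_citc_identical_columns_is_one():
    x = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
    sm = ScoreMatrix(x)
    for item in (1, 2, 3):
        assert its.citc(sm, item) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "item, expected",
    [(1, 0.436435780472), (2, 0.683130051064), (3, 0.547722557505)],
)
def test_citc_f1_frozen_values(f1, item, expected):
    assert its.citc(f1, item) == pytest.approx(expected, abs=1e-10)
    assert its.citc(f1, item) == pytest.approx(
        oracle_citc(f1.values.astype(float), item - 1), abs=1e-12
    )


def test_citc_zero_variance_errors():
    x = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]])
    with pytest.raises(UndefinedValueError, match="item 1"):
        its.citc(ScoreMatrix(x), 1)


def test_coefficient_alpha_examples(f1):
    two_same = ScoreMatrix(np.array([[1, 1], [0, 0], [1, 1], [0, 0]]))
    assert its.coefficient_alpha(two_same) == pytest.approx(1.0)
    assert its.coefficient_alpha(f1) == pytest.approx(0.7183098591549296, abs=1e-12)
    assert its.coefficient_alpha(f1) == pytest.approx(
        oracle_alpha(f1.values.astype(float)), abs=1e-12
    )
    with pytest.raises(UndefinedValueError):
        its.coefficient_alpha(ScoreMatrix(np.array([[0], [1]])))


def test_alpha_population_independent_items_is_zero():
    params = its.ItemParams(alpha=np.array([1.0, 1.0]), beta=np.zeros(2))
    moments = its.theoretical_moments(params)
    pop = PopulationScores(moments)
    pop._cov = np.diag(np.diag(pop._cov))  # force independence
    assert its.coefficient_alpha(pop) == pytest.approx(0.0, abs=1e-12)


# -- method CA ---------------------------------------------------------------


def test_ca_identical_columns_is_one():
    x = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
    assert its.method_ca(ScoreMatrix(x), 2) == pytest.approx(1.0)


def test_ca_f1_frozen_values(f1):
    assert its.method_ca(f1, 1) == pytest.approx(0.25396825396825, abs=1e-10)
    # raw value above 1 is reported, not truncated
    assert its.method_ca(f1, 2) == pytest.approx(1.08888888888889, abs=1e-10)
    assessment = its.assess_all(f1, "CA")
    assert "ca_above_one" in assessment.diagnostics[2]
    assert 1 not in assessment.diagnostics


def test_ca_attenuation_identity_random_data(f1):
    """rho_CA * alpha_rest == citc^2, exactly, whenever both are defined."""
    rng = np.random.default_rng(11)
    mats = [f1.values] + [random_binary_matrix(rng, 40, 6) for _ in range(25)]
    for x in mats:
        sm = ScoreMatrix(x)
        for item in sm.item_labels:
            rest = [l for l in sm.item_labels if l != item]
            try:
                ca = its.method_ca(sm, item)
            except UndefinedValueError:  # incoherent rest score: identity undefined
                continue
            lhs = ca * its.coefficient_alpha(sm.subset(rest))
            assert lhs == pytest.approx(its.citc(sm, item) ** 2, abs=1e-12)


# -- method lambda-6 ---------------------------------------------------------


def test_lambda6_identical_columns_raise():
    x = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
    with pytest.raises(SingularCovarianceError, match="collinear"):
        its.method_lambda6(ScoreMatrix(x), 1)


def test_lambda6_f1_frozen_values(f1):
    assert its.method_lambda6(f1, 1) == pytest.approx(0.238095238095, abs=1e-10)
    assert its.method_lambda6(f1, 2) == pytest.approx(0.466666666667, abs=1e-10)
    assert its.method_lambda6(f1, 3) == pytest.approx(0.36, abs=1e-10)


def test_lambda6_matrix_inverse_equals_regression(f1):
    rng = np.random.default_rng(5)
    mats = [f1.values] + [random_binary_matrix(rng, 60, 8) for _ in range(25)]
    for x in mats:
        sm = ScoreMatrix(x)
        for item in sm.item_labels:
            assert its.method_lambda6(sm, item) == pytest.approx(
                oracle_lambda6(x.astype(float), item - 1), abs=1e-10
            )


def test_lambda6_population_independent_item_is_zero():
    params = its.ItemParams(alpha=np.array([1.0, 1.0, 1.0]), beta=np.zeros(3))
    pop = PopulationScores(its.theoretical_moments(params))
    cov = pop._cov.copy()
    cov[0, 1:] = cov[1:, 0] = 0.0  # item 1 independent of the others
    pop._cov = cov
    assert its.method_lambda6(pop, 1) == pytest.approx(0.0, abs=1e-12)


# -- method MS ---------------------------------------------------------------


def test_ms_identical_columns_is_one():
    """All popularities tie, so the tied items estimate the repeat pass rate."""
    x = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
    sm = ScoreMatrix(x)
    for item in (1, 2, 3):
        assert its.method_ms(sm, item) == pytest.approx(1.0)
    assessment = its.assess_all(sm, "MS")
    assert all("ms_tied_target" in assessment.diagnostics[l] for l in (1, 2, 3))


@pytest.mark.parametrize("item", [1, 2, 3])
def test_ms_f2_hand_computed(f2, item):
    """Distinct popularities (7/9, 6/9, 3/9) exercise both edge rules and
    the interior interpolation; expected values traced by hand."""
    p = f2.values.mean(axis=0)
    pj = (f2.values.astype(float).T @ f2.values) / f2.N
    if item == 1:  # most popular: conditional rate via item 2
        ph = pj[0, 1] * p[0] / p[1]
    elif item == 2:  # interior: line through items 1 and 3
        ph = pj[1, 2] + (p[1] - p[2]) * (pj[1, 0] - pj[1, 2]) / (p[0] - p[2])
    else:  # least popular: conditional rate via item 2
        ph = pj[2, 1] * p[2] / p[1]
    ph = min(max(ph, max(0.0, 2 * p[item - 1] - 1)), p[item - 1])
    expected = (ph - p[item - 1] ** 2) / (p[item - 1] * (1 - p[item - 1]))
    assert its.method_ms(f2, item) == pytest.approx(expected, abs=1e-12)
    assert its.method_ms(f2, item) == pytest.approx(0.25, abs=1e-12)


def test_ms_constant_column_errors():
    x = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]])
    with pytest.raises(UndefinedValueError, match="item 1"):
        its.method_ms(ScoreMatrix(x), 1)


def test_ms_bounded_on_random_data(small_params):
    """After clamping, MS reliabilities never exceed 1 (1000 random data sets)."""
    rng = np.random.default_rng(17)
    for rep in range(1000):
        sm = its.generate_scores(small_params, 200, rng)
        values = its.assess_all(sm, "MS").values
        assert np.all(values <= 1 + 1e-12)
        assert np.all(values >= -1 - 1e-12)


# -- assess_all and generic behaviour ----------------------------------------


def test_assess_all_matches_elementwise_calls(f1):
    for method, fn in [
        ("CITC", its.citc),
        ("CA", its.method_ca),
        ("L6", its.method_lambda6),
        ("MS", its.method_ms),
    ]:
        a = its.assess_all(f1, method)
        for label, value in zip(a.item_labels, a.values):
            assert value == pytest.approx(fn(f1, int(label)), abs=1e-14)


def test_assess_all_unknown_method(f1):
    with pytest.raises(ValueError, match="unknown method"):
        its.assess_all(f1, "XYZ")


def test_assessment_csv(tmp_path, f1):
    a = its.assess_all(f1, "CA")
    path = tmp_path / "a.csv"
    a.to_csv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "item,method,value,flags"
    assert len(lines) == 4


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_permutation_invariance(seed):
    """Estimators ignore person order and follow item labels under column swaps."""
    rng = np.random.default_rng(seed)
    x = random_binary_matrix(rng, 30, 5)
    sm = ScoreMatrix(x)
    rows = rng.permutation(30)
    cols = rng.permutation(5)
    shuffled = ScoreMatrix(x[rows][:, cols], item_labels=cols + 1)
    for method in its.METHODS:
        try:
            base = its.assess_all(sm, method)
        except (UndefinedValueError, SingularCovarianceError):
            continue
        perm = its.assess_all(shuffled, method)
        for label, value in zip(perm.item_labels, perm.values):
            k = int(np.flatnonzero(base.item_labels == label)[0])
            assert value == pytest.approx(base.values[k], abs=1e-12)


def test_stats_view_matches_subset(f2):
    view = _StatsView(f2, np.array([2, 0]))
    sub = f2.subset([3, 1])
    np.testing.assert_allclose(view.cov(), sub.cov())
    np.testing.assert_allclose(view.joint(), sub.joint())
    np.testing.assert_allclose(view.popularity(), sub.popularity())


# -- large-sample consistency ------------------------------------------------


def test_large_sample_consistency(big_sample, small_moments):
    """Sample CITC, CA and lambda-6 at N = 100k match population counterparts."""
    pop = PopulationScores(small_moments)
    for item in (1, 7, 14, 20):
        assert its.citc(big_sample, item) == pytest.approx(
            its.citc(pop, item), abs=0.01
        )
        assert its.method_ca(big_sample, item) == pytest.approx(
            its.method_ca(pop, item), abs=0.01
        )
        assert its.method_lambda6(big_sample, item) == pytest.approx(
            its.method_lambda6(pop, item), abs=0.01
        )


def test_lambda6_is_conservative(small_params, small_moments):
    """Mean lambda-6 does not exceed the exact item reliability (500 samples)."""
    rng = np.random.default_rng(23)
    totals = np.zeros(small_params.J)
    n_rep = 500
    for _ in range(n_rep):
        sm = its.generate_scores(small_params, 1000, rng)
        totals += its.assess_all(sm, "L6").values
    mean_l6 = totals / n_rep
    rho = np.array(
        [its.theoretical_item_reliability(small_moments, i + 1) for i in range(20)]
    )
    assert np.all(mean_l6 <= rho + 0.01)
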