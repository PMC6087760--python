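import itertools

import numpy as np
import pandas as pd
import pytest

from figana.irt import (
    LLTM,
    ConvergenceError,
    EstimationError,
    IdentifiabilityError,
    QMatrix,
    RaschModel,
    ResponseMatrix,
    andersen_lr,
    compare_deviance,
    cronbach_alpha,
    esf,
    fit_lltm_cml,
    fit_rasch_cml,
    lltm_predict,
    wald_item_test,
)
from figana.response_simulator import SimConfig, simulate_responses

from conftest import brute_conditional_loglik, brute_max_conditional_loglik


def two_item_data(n10=20, n01=10, n_extreme=6):
    rows = [[1, 0]] * n10 + [[0, 1]] * n01
    rows += [[1, 1], [0, 0]] * (n_extreme // 2)
    return ResponseMatrix(np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# elementary symmetric functions


def test_esf_matches_direct_expansion_up_to_ten_items():
    rng = np.random.default_rng(0)
    for n in range(2, 11):
        eps = rng.uniform(0.2, 5.0, size=n)
        g = esf(eps)
        direct = np.zeros(n + 1)
        for r in range(n + 1):
            direct[r] = sum(
                np.prod(eps[list(c)]) for c in itertools.combinations(range(n), r)
            )
        np.testing.assert_allclose(g, direct, rtol=1e-10)


# ---------------------------------------------------------------------------
# Rasch CML


def test_two_item_closed_form_difficulty_difference():
    """With two items the CML estimate satisfies b2 - b1 = log(n10 / n01)."""
    fit = fit_rasch_cml(two_item_data(20, 10))
    assert fit.beta[1] - fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-8)
    assert abs(fit.beta.mean()) < 1e-10


def test_conditional_optimum_matches_brute_force():
    """The fitted conditional likelihood equals an independent brute-force
    pattern-enumeration maximum on small banks."""
    rng = np.random.default_rng(5)
    for n_items in (3, 4, 5):
        values = (rng.random((30, n_items)) < rng.uniform(0.3, 0.7, n_items)).astype(float)
        data = ResponseMatrix(values)
        fit = fit_rasch_cml(data)
        assert fit.cond_loglik == pytest.approx(
            brute_conditional_loglik(values, fit.beta), abs=1e-9
        )
        assert fit.cond_loglik == pytest.approx(
            brute_max_conditional_loglik(values), abs=1e-6
        )


def test_item_permutation_equivariance():
    rng = np.random.default_rng(3)
    values = (rng.random((200, 5)) < [0.3, 0.5, 0.6, 0.4, 0.7]).astype(float)
    perm = [4, 2, 0, 1, 3]
    f1 = fit_rasch_cml(ResponseMatrix(values))
    f2 = fit_rasch_cml(ResponseMatrix(values[:, perm]))
    np.testing.assert_allclose(f2.beta, f1.beta[perm], atol=1e-8)


def test_difficulty_recovery_at_large_n():
    beta = np.linspace(-2, 2, 23)
    data = simulate_responses(beta, SimConfig(n_persons=1000, seed=21))
    fit = fit_rasch_cml(data)
    assert np.corrcoef(fit.beta, beta - beta.mean())[0, 1] > 0.98


def test_extreme_scores_are_flagged_and_excluded():
    data = two_item_data(12, 8, n_extreme=10)
    assert data.extreme_persons().sum() == 10
    model = RaschModel(data)
    assert model._problem.n_informative == 20


def test_no_informative_persons_raises():
    values = np.array([[1, 1, 1], [0, 0, 0]], dtype=float)
    with pytest.raises(EstimationError):
        fit_rasch_cml(ResponseMatrix(values))


def test_missing_responses_handled_pairwise():
    beta = np.linspace(-1, 1, 6)
    data = simulate_responses(beta, SimConfig(n_persons=800, seed=2))
    v = data.values.copy()
    v[:200, 0] = np.nan
    v[200:400, 3] = np.nan
    fit = fit_rasch_cml(ResponseMatrix(v))
    assert np.corrcoef(fit.beta, beta - beta.mean())[0, 1] > 0.95
    assert fit.cond_loglik == pytest.approx(
        brute_conditional_loglik(v, fit.beta), abs=1e-8
    )


def test_summary_mentions_model_and_items():
    fit = fit_rasch_cml(two_item_data())
    text = fit.summary()
    assert "conditional" in text.lower()
    assert "I1" in text


# ---------------------------------------------------------------------------
# LLTM


def saturated_q(n_items):
    """Reference-item reparameterization: item n anchored at zero."""
    w = np.zeros((n_items, n_items - 1))
    w[: n_items - 1, :] = np.eye(n_items - 1)
    return QMatrix(w)


def test_saturated_lltm_reproduces_rasch():
    rng = np.random.default_rng(8)
    values = (rng.random((400, 5)) < [0.3, 0.45, 0.6, 0.5, 0.7]).astype(float)
    data = ResponseMatrix(values)
    rasch = fit_rasch_cml(data)
    lltm = fit_lltm_cml(data, saturated_q(5))
    assert lltm.cond_loglik == pytest.approx(rasch.cond_loglik, abs=1e-8)
    np.testing.assert_allclose(lltm.beta_hat_centered, rasch.beta, atol=1e-6)
    comp = compare_deviance(rasch, lltm)
    assert comp.statistic == pytest.approx(0.0, abs=1e-6)


def test_single_rule_items_reduce_to_rule_difficulty():
    w = np.zeros((6, 2))
    w[:3, 0] = 1
    w[3:, 1] = 1
    q = QMatrix(w)
    beta = lltm_predict(q, [0.7, -0.4])
    np.testing.assert_allclose(beta, [0.7] * 3 + [-0.4] * 3)


def test_lltm_predict_matches_row_summation():
    rng = np.random.default_rng(1)
    w = (rng.random((23, 9)) < 0.4).astype(float)
    w[:9, :9] = np.eye(9)  # guarantee no all-zero column
    q = QMatrix(w)
    alpha = rng.normal(size=9)
    expected = np.array([sum(w[i, j] * alpha[j] for j in range(9)) for i in range(23)])
    np.testing.assert_allclose(lltm_predict(q, alpha), expected, rtol=1e-12)


def test_lltm_predict_zero_row_gives_zero():
    w = np.zeros((4, 2))
    w[0, 0] = w[1, 1] = w[2, 0] = 1  # row 3 stays empty
    q = QMatrix(w)
    assert lltm_predict(q, [1.2, -0.5])[3] == 0.0


def test_lltm_recovers_alpha_within_three_se(responses23, q9):
    from figana.response_simulator import PUBLISHED_RULE_DIFFICULTIES

    fit = fit_lltm_cml(responses23, q9)
    z = (fit.alpha - PUBLISHED_RULE_DIFFICULTIES) / fit.se
    assert np.all(np.abs(z) < 3)


def test_rank_deficient_q_rejected():
    w = np.zeros((6, 2))
    w[:, 0] = 1
    w[:, 1] = 1  # duplicated column
    with pytest.raises(IdentifiabilityError):
        LLTM(ResponseMatrix(np.eye(6)[:5] * 0 + (np.arange(30).reshape(5, 6) % 2)), QMatrix(w))


def test_constant_spanning_q_rejected():
    w = np.ones((6, 1))  # beta identical across items: only a shift, unidentified
    rng = np.random.default_rng(0)
    values = (rng.random((50, 6)) < 0.5).astype(float)
    with pytest.raises(IdentifiabilityError):
        LLTM(ResponseMatrix(values), QMatrix(w))


def test_q_matrix_validation():
    with pytest.raises(ValueError):
        QMatrix(np.zeros((4, 2)))  # all-zero columns
    with pytest.raises(ValueError):
        QMatrix(np.ones((3, 3)))  # p not below n_items
    with pytest.raises(ValueError):
        QMatrix(np.full((4, 2), 0.5))  # non-binary


# ---------------------------------------------------------------------------
# model tests


def test_andersen_df_and_zero_statistic_on_identical_halves():
    rng = np.random.default_rng(7)
    half = (rng.random((150, 8)) < np.linspace(0.3, 0.7, 8)).astype(float)
    doubled = np.vstack([half, half])
    labels = np.repeat([0, 1], 150)
    res = andersen_lr(ResponseMatrix(doubled), split=labels)
    assert res.df == 7
    assert res.statistic == pytest.approx(0.0, abs=1e-6)
    assert res.p_value == pytest.approx(1.0, abs=1e-6)


def test_andersen_median_split_ties_to_lower_group():
    beta = np.linspace(-1, 1, 10)
    data = simulate_responses(beta, SimConfig(n_persons=400, seed=6))
    res = andersen_lr(data)
    assert res.df == 9
    assert 0.0 <= res.p_value <= 1.0


def test_wald_zero_on_identical_halves():
    rng = np.random.default_rng(9)
    half = (rng.random((120, 6)) < np.linspace(0.35, 0.65, 6)).astype(float)
    doubled = np.vstack([half, half])
    labels = np.repeat([0, 1], 120)
    res = wald_item_test(ResponseMatrix(doubled), split=labels)
    np.testing.assert_allclose(res.z, 0.0, atol=1e-6)


def test_wald_flags_shifted_item():
    """An item whose difficulty shifts by +1 in the second group should show
    the largest |z| in the clear majority of replications."""
    beta = np.linspace(-1, 1, 12)
    hits = 0
    n_reps = 30
    for rep in range(n_reps):
        g1 = simulate_responses(beta, SimConfig(n_persons=300, seed=1000 + rep))
        shifted = beta.copy()
        shifted[4] += 1.0
        g2 = simulate_responses(shifted, SimConfig(n_persons=300, seed=5000 + rep))
        data = ResponseMatrix(np.vstack([g1.values, g2.values]))
        labels = np.repeat([0, 1], 300)
        res = wald_item_test(data, split=labels)
        if np.argmax(np.abs(res.z)) == 4:
            hits += 1
    assert hits / n_reps > 0.9


def test_deviance_df_convention(responses23, q5, q9):
    rasch = fit_rasch_cml(responses23)
    assert compare_deviance(rasch, fit_lltm_cml(responses23, q5)).df == 17
    assert compare_deviance(rasch, fit_lltm_cml(responses23, q9)).df == 13


def test_lltm_never_beats_rasch(responses23, q5):
    rasch = fit_rasch_cml(responses23)
    lltm = fit_lltm_cml(responses23, q5)
    assert lltm.cond_loglik <= rasch.cond_loglik + 1e-8


# ---------------------------------------------------------------------------
# Cronbach's alpha


def test_alpha_is_one_for_identical_columns():
    col = np.array([1, 0, 1, 1, 0, 1, 0, 1], dtype=float)
    data = np.column_stack([col, col, col])
    assert cronbach_alpha(data) == pytest.approx(1.0)


def test_alpha_near_zero_for_independent_coins():
    rng = np.random.default_rng(12)
    data = (rng.random((20000, 10)) < 0.5).astype(float)
    assert abs(cronbach_alpha(data)) < 0.05


def test_alpha_matches_hand_computation():
    # two items over five persons; variances computed by hand (ddof=1):
    # item1 = (1,1,0,0,1), var = 0.3;  item2 = (1,0,0,1,1), var = 0.3
    # totals = (2,1,0,1,2), var = 0.7;  alpha = 2 * (1 - 0.6/0.7) = 2/7
    data = np.array([[1, 1], [1, 0], [0, 0], [0, 1], [1, 1]], dtype=float)
    assert cronbach_alpha(data) == pytest.approx(2.0 / 7.0)


def test_alpha_undefined_for_zero_total_variance():
    data = np.array([[1, 0], [1, 0], [1, 0]], dtype=float)
    with pytest.raises(ZeroDivisionError):
        cronbach_alpha(data)


def test_alpha_uses_complete_rows_only():
    data = np.array([[1, 1], [1, 0], [0, 0], [np.nan, 1], [0, 1], [1, 1]])
    complete = data[~np.isnan(data).any(axis=1)]
    assert cronbach_alpha(ResponseMatrix(data)) == pytest.approx(
        cronbach_alpha(complete)
    )
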