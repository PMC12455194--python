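"""Tests for propensity scores, caliper matching, PMM imputation and
Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

from deltalcs import (
    MissingnessSpec,
    apply_missingness,
    bivariate_config,
    bivariate_lcs_spec,
    estimate_propensity,
    fit_ml,
    generate_longitudinal,
    impute_pmm,
    match_nearest,
    pool_rubin,
)
from deltalcs.missing import attrition_table


def damped_newton_logistic(X, y, max_iter=200, tol=1e-12):
    """Independent logistic-regression oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, grad)
        while np.any(~np.isfinite(X @ (beta + step))):
            step /= 2
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# propensity
# ---------------------------------------------------------------------------

def test_null_model_scores_half():
    rng = np.random.default_rng(0)
    n = 2000
    table = pd.DataFrame({
        "x": rng.normal(size=n),
        "member": rng.integers(0, 2, size=n),
    })
    scores = estimate_propensity(table, ["x"], "member")
    assert abs(scores.mean() - table["member"].mean()) < 0.01
    assert scores.std() < 0.05


def test_intercept_only_model_returns_prevalence():
    rng = np.random.default_rng(1)
    table = pd.DataFrame({"member": (rng.random(500) < 0.3).astype(int)})
    scores = estimate_propensity(table, [], "member")
    np.testing.assert_allclose(scores, table["member"].mean(), atol=1e-9)


def test_coefficients_match_newton_oracle():
    rng = np.random.default_rng(0)
    n = 20
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    eta = 0.3 + 0.8 * x1 - 0.5 * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    if y.min() == y.max():  # fixed seed keeps both classes; guard anyway
        y[0] = 1 - y[0]
    table = pd.DataFrame({"x1": x1, "x2": x2, "member": y})
    scores = estimate_propensity(table, ["x1", "x2"], "member")
    X = np.column_stack([np.ones(n), x1, x2])
    beta = damped_newton_logistic(X, y)
    np.testing.assert_allclose(scores, 1 / (1 + np.exp(-X @ beta)), atol=1e-6)


def test_complete_separation_rejected():
    table = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20) + 5],
                          "member": np.r_[np.zeros(20), np.ones(20)]})
    with pytest.raises(ValueError, match="separation"):
        estimate_propensity(table, ["x"], "member")


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_identical_scores_full_match():
    scores = pd.Series(np.r_[np.linspace(0.2, 0.8, 10), np.linspace(0.2, 0.8, 10)])
    member = pd.Series([1] * 10 + [0] * 10)
    res = match_nearest(scores, member, caliper=1e-9)
    assert res.match_rate == 1.0
    assert len(res.pairs) == 10


def test_zero_caliper_distinct_scores_no_match():
    scores = pd.Series([0.1, 0.2, 0.3, 0.4])
    member = pd.Series([1, 1, 0, 0])
    res = match_nearest(scores, member, caliper=0.0)
    assert res.pairs == []
    assert res.match_rate == 0.0


def test_three_vs_three_toy_enumeration():
    """Exhaustively checkable toy: greedy descending matching pairs
    0.2<->0.21 and 0.1<->0.15 under caliper 0.06; 0.9 stays unmatched."""
    scores = pd.Series([0.1, 0.2, 0.9, 0.15, 0.21, 0.5],
                       index=list("abcdef"))
    member = pd.Series([1, 1, 1, 0, 0, 0], index=list("abcdef"))
    res = match_nearest(scores, member, caliper=0.06, order="descending")
    assert set(res.pairs) == {("b", "e"), ("a", "d")}
    assert res.match_rate == pytest.approx(2 / 3)


def test_matching_without_replacement_injective():
    rng = np.random.default_rng(3)
    scores = pd.Series(rng.random(300))
    member = pd.Series((rng.random(300) < 0.3).astype(int))
    res = match_nearest(scores, member, caliper=0.05)
    left = [a for a, _ in res.pairs]
    right = [b for _, b in res.pairs]
    assert len(set(left)) == len(left)
    assert len(set(right)) == len(right)
    for a, b in res.pairs:
        assert abs(scores[a] - scores[b]) <= 0.05


# ---------------------------------------------------------------------------
# PMM
# ---------------------------------------------------------------------------

def test_no_missing_cells_identical_copies():
    table = generate_longitudinal(bivariate_config(seed=4), 200)
    imp = impute_pmm(table, ("thal_t2_ml",), ("thal_t1_ml",), m=3, seed=5)
    assert imp.m == 3
    for t in imp.tables:
        pd.testing.assert_frame_equal(t, table)


def test_imputed_values_are_observed_donor_values():
    table = generate_longitudinal(bivariate_config(seed=6), 500)
    masked = apply_missingness(
        table, MissingnessSpec(rate=0.3, target_columns=("hipp_t2_ml",), seed=7))
    observed = set(masked["hipp_t2_ml"].dropna())
    imp = impute_pmm(masked, ("hipp_t2_ml",), ("hipp_t1_ml", "thal_t1_ml"),
                     m=4, seed=8)
    was_missing = masked["hipp_t2_ml"].isna()
    for t in imp.tables:
        assert t["hipp_t2_ml"].notna().all()
        assert set(t.loc[was_missing, "hipp_t2_ml"]) <= observed
        # observed cells untouched
        pd.testing.assert_series_equal(
            t.loc[~was_missing, "hipp_t2_ml"], masked.loc[~was_missing, "hipp_t2_ml"])


def test_pmm_mcar_pooled_mean_unbiased():
    """Pooled mean of an MCAR-masked column stays within 2 pooled SEs of
    the complete-data mean."""
    table = generate_longitudinal(bivariate_config(seed=9), 2000)
    truth = table["hipp_t2_ml"].mean()
    masked = apply_missingness(
        table, MissingnessSpec(rate=0.3, target_columns=("hipp_t2_ml",), seed=10))
    imp = impute_pmm(masked, ("hipp_t2_ml",), ("hipp_t1_ml", "thal_t1_ml"),
                     m=40, seed=11)
    ests = [t["hipp_t2_ml"].mean() for t in imp.tables]
    vars_ = [t["hipp_t2_ml"].var(ddof=1) / len(t) for t in imp.tables]
    pooled = pool_rubin(ests, vars_)
    assert abs(pooled.estimate - truth) < 2 * pooled.se


def test_pmm_rejects_underdetermined_model():
    table = pd.DataFrame({"y": [1.0, np.nan, 2.0], "x": [0.1, 0.2, 0.3]})
    with pytest.raises(ValueError, match="observed rows"):
        impute_pmm(table, ("y",), ("x",), m=1, seed=0)


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

def test_rubin_identical_estimates():
    pe = pool_rubin([2.0, 2.0, 2.0], [0.3, 0.3, 0.3])
    assert pe.between_var == 0.0
    assert pe.se == pytest.approx(np.sqrt(0.3))


def test_rubin_hand_arithmetic():
    pe = pool_rubin([1.0, 2.0], [0.1, 0.1])
    assert pe.estimate == pytest.approx(1.5)
    assert pe.total_var == pytest.approx(0.1 + 1.5 * 0.5)


def test_rubin_total_at_least_within():
    rng = np.random.default_rng(12)
    for _ in range(20):
        q = rng.normal(size=8)
        u = rng.random(8) + 0.05
        pe = pool_rubin(q, u)
        assert pe.total_var >= pe.within_var - 1e-12


def test_rubin_rejects_misaligned():
    with pytest.raises(ValueError, match="aligned"):
        pool_rubin([1.0, 2.0], [0.1])


def test_barnard_rubin_df_finite_with_dfcom():
    pe = pool_rubin([1.0, 1.2, 0.9], [0.2, 0.2, 0.2], dfcom=100)
    assert np.isfinite(pe.df)
    assert pe.df > 0


# ---------------------------------------------------------------------------
# integration: MI -> LCS recovery
# ---------------------------------------------------------------------------

def test_mi_lcs_loop_recovers_coupling():
    """Imputing MCAR follow-ups then pooling bivariate LCS fits recovers
    the generating thalamus->hippocampus coupling."""
    spec = bivariate_lcs_spec()
    table = generate_longitudinal(bivariate_config(seed=13), 2000)
    masked = apply_missingness(table, MissingnessSpec(rate=0.5, seed=14))
    imp = impute_pmm(masked, ("thal_t2_ml", "hipp_t2_ml"),
                     ("thal_t1_ml", "hipp_t1_ml"), m=10, seed=15)
    ests, vars_ = [], []
    for t in imp.tables:
        f = fit_ml(spec, t)
        ests.append(f.estimates["gamma_t_dh"])
        vars_.append(f.ses["gamma_t_dh"] ** 2)
    pooled = pool_rubin(ests, vars_, dfcom=2000 - spec.n_free)
    assert abs(pooled.estimate - (-0.048)) < 3 * pooled.se
    assert pooled.p < 0.05


def test_attrition_table_columns():
    table = generate_longitudinal(bivariate_config(seed=16), 200)
    mask = table.index < 100
    out = attrition_table(table, mask, ["thal_t1_ml", "hipp_t1_ml"])
    assert list(out.columns) == ["covariate", "full_mean", "full_sd",
                                 "retained_mean", "retained_sd", "difference"]
    assert len(out) == 2
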