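"""Unit and property tests for the structural-equation LCS engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from deltalcs import (
    LCSModelSpec,
    Parameter,
    bivariate_config,
    bivariate_lcs_spec,
    closed_form_start,
    fit_fiml,
    fit_ml,
    fit_multigroup,
    generate_longitudinal,
    implied_moments,
    ml_discrepancy,
    multivariate_age_config,
    multivariate_age_spec,
    saturated_spec,
    standard_errors,
    theta_from_config,
)

VOLUME_COLS = ["thal_t1_ml", "thal_t2_ml", "hipp_t1_ml", "hipp_t2_ml"]


def difference_score_regression(table, atrophy_positive=True):
    """Independent oracle: multivariate OLS of observed change scores on
    the two baselines, with n-1 moment denominators throughout."""
    t1 = table["thal_t1_ml"].to_numpy()
    h1 = table["hipp_t1_ml"].to_numpy()
    sign = 1.0 if atrophy_positive else -1.0
    d = np.column_stack([
        sign * (t1 - table["thal_t2_ml"].to_numpy()),
        sign * (h1 - table["hipp_t2_ml"].to_numpy()),
    ])
    X = np.column_stack([np.ones(len(t1)), t1, h1])
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ beta
    psi = resid.T @ resid / (len(t1) - 1)
    base = np.column_stack([t1, h1])
    return {
        "mu_thal": t1.mean(), "mu_hipp": h1.mean(),
        "var_thal": np.var(t1, ddof=1), "var_hipp": np.var(h1, ddof=1),
        "phi_ht": np.cov(t1, h1, ddof=1)[0, 1],
        "alpha_thal": beta[0, 0], "alpha_hipp": beta[0, 1],
        "beta_t": beta[1, 0], "gamma_h_dt": beta[2, 0],
        "gamma_t_dh": beta[1, 1], "beta_h": beta[2, 1],
        "psi_thal": psi[0, 0], "psi_hipp": psi[1, 1], "rho_ht": psi[0, 1],
    }


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------

def test_spec_rejects_bad_inputs():
    with pytest.raises(ValueError, match="undeclared"):
        LCSModelSpec(observed=("a",), fixed_paths=(("a", "b", 1.0),))
    with pytest.raises(ValueError, match=r"\+1 or -1"):
        LCSModelSpec(observed=("a", "b"), fixed_paths=(("a", "b", 2.0),))
    with pytest.raises(ValueError, match="unique"):
        LCSModelSpec(
            observed=("a", "b"),
            params=(Parameter("mean", "a", "a", "m"),
                    Parameter("mean", "b", "b", "m")),
        )


def test_spec_json_roundtrip(biv_spec):
    again = LCSModelSpec.from_json(biv_spec.to_json())
    assert again == biv_spec


def test_theta_validation(biv_spec):
    with pytest.raises(ValueError, match="incomplete"):
        biv_spec.theta_array({"mu_thal": 1.0})
    bad = dict.fromkeys(biv_spec.labels, 0.5)
    bad["phi_ht"] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        implied_moments(biv_spec, bad)


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

def test_saturated_implied_moments_are_theta_verbatim():
    spec = saturated_spec(["a", "b", "c"])
    theta = {"mu[a]": 1.0, "mu[b]": -2.0, "mu[c]": 0.5,
             "var[a]": 2.0, "var[b]": 1.0, "var[c]": 3.0,
             "cov[a,b]": 0.3, "cov[a,c]": -0.2, "cov[b,c]": 0.7}
    mu, sigma = implied_moments(spec, theta)
    np.testing.assert_allclose(mu, [1.0, -2.0, 0.5])
    np.testing.assert_allclose(
        sigma, [[2.0, 0.3, -0.2], [0.3, 1.0, 0.7], [-0.2, 0.7, 3.0]])


@pytest.mark.parametrize("gamma_t_dh,gamma_h_dt", [(0.0, 0.0), (-0.3, 0.4)])
def test_baseline_block_is_exogenous(biv_spec, gamma_t_dh, gamma_h_dt):
    """The implied baseline covariance block never depends on the
    coupling parameters: baselines are exogenous."""
    theta = theta_from_config(bivariate_config())
    theta["gamma_t_dh"], theta["gamma_h_dt"] = gamma_t_dh, gamma_h_dt
    _, sigma = implied_moments(biv_spec, theta)
    idx = [biv_spec.observed.index(c) for c in ("thal_t1_ml", "hipp_t1_ml")]
    block = sigma[np.ix_(idx, idx)]
    np.testing.assert_allclose(
        block, [[theta["var_thal"], theta["phi_ht"]],
                [theta["phi_ht"], theta["var_hipp"]]], atol=1e-12)


def test_implied_moments_match_monte_carlo(biv_spec):
    """Large-sample generator moments agree with the analytic implied
    moments at the same parameters (3 Monte-Carlo SEs)."""
    cfg = bivariate_config(seed=314)
    n = 1_000_000
    table = generate_longitudinal(cfg, n)
    mu, sigma = implied_moments(biv_spec, theta_from_config(cfg))
    y = table[list(biv_spec.observed)].to_numpy()
    mean = y.mean(axis=0)
    cov = np.cov(y, rowvar=False)
    sd = np.sqrt(np.diag(sigma))
    np.testing.assert_allclose(mean, mu, atol=max(3 * sd.max() / np.sqrt(n), 1e-3))
    for i in range(4):
        for j in range(4):
            mcse = np.sqrt((sigma[i, i] * sigma[j, j] + sigma[i, j] ** 2) / n)
            assert abs(cov[i, j] - sigma[i, j]) < max(3 * mcse, 1e-3)


def test_follow_up_mean_is_baseline_minus_change(biv_spec):
    """Atrophy-positive sign convention in expectation."""
    cfg = bivariate_config()
    mu, _ = implied_moments(biv_spec, theta_from_config(cfg))
    named = dict(zip(biv_spec.observed, mu))
    assert named["thal_t2_ml"] == pytest.approx(
        named["thal_t1_ml"] - cfg.change_means[0], abs=1e-10)
    assert named["hipp_t2_ml"] == pytest.approx(
        named["hipp_t1_ml"] - cfg.change_means[1], abs=1e-10)


# ---------------------------------------------------------------------------
# ML discrepancy
# ---------------------------------------------------------------------------

def test_discrepancy_zero_at_sample_moments(toy_bivariate_data):
    spec = saturated_spec(["x1", "x2"])
    y = toy_bivariate_data.to_numpy()
    mean = y.mean(axis=0)
    S = np.cov(y, rowvar=False, ddof=1)
    theta = {"mu[x1]": mean[0], "mu[x2]": mean[1], "var[x1]": S[0, 0],
             "var[x2]": S[1, 1], "cov[x1,x2]": S[0, 1]}
    assert ml_discrepancy(spec, theta, mean, S) == pytest.approx(0.0, abs=1e-12)


def test_discrepancy_matches_hand_formula():
    """2-variable toy against scalar arithmetic with explicit 2x2
    determinants and inverses."""
    spec = saturated_spec(["x1", "x2"])
    S = np.array([[2.0, 0.5], [0.5, 1.0]])
    mbar = np.array([1.0, -1.0])
    theta = {"mu[x1]": 0.8, "mu[x2]": -1.3, "var[x1]": 1.8,
             "var[x2]": 1.2, "cov[x1,x2]": 0.3}
    sig = np.array([[1.8, 0.3], [0.3, 1.2]])
    det_sig = 1.8 * 1.2 - 0.3**2
    det_s = 2.0 * 1.0 - 0.5**2
    inv = np.array([[1.2, -0.3], [-0.3, 1.8]]) / det_sig
    diff = mbar - np.array([0.8, -1.3])
    expect = (np.log(det_sig) + (S[0, 0] * inv[0, 0] + 2 * S[0, 1] * inv[0, 1]
              + S[1, 1] * inv[1, 1]) + diff @ inv @ diff - np.log(det_s) - 2)
    assert ml_discrepancy(spec, theta, mbar, S) == pytest.approx(expect, rel=1e-12)
    assert expect > 0


def test_discrepancy_permutation_invariant(small_cohort, biv_spec):
    """F is unchanged by a simultaneous reordering of spec and data."""
    y = small_cohort[VOLUME_COLS].to_numpy()
    mean, S = y.mean(axis=0), np.cov(y, rowvar=False, ddof=1)
    theta = theta_from_config(bivariate_config())
    f1 = ml_discrepancy(biv_spec, theta, mean, S)
    perm = [2, 3, 0, 1]  # hippocampus first
    spec2 = bivariate_lcs_spec(thal=("thal_t1_ml", "thal_t2_ml"),
                               hipp=("hipp_t1_ml", "hipp_t2_ml"))
    spec2 = LCSModelSpec(
        observed=tuple(np.array(spec2.observed)[perm]),
        latent=spec2.latent, fixed_paths=spec2.fixed_paths, params=spec2.params)
    f2 = ml_discrepancy(spec2, theta, mean[perm], S[np.ix_(perm, perm)])
    assert f2 == pytest.approx(f1, rel=1e-10)


def test_discrepancy_rejects_singular_implied(biv_spec):
    theta = theta_from_config(bivariate_config())
    theta["var_thal"] = 0.0
    theta["phi_ht"] = 0.0
    y = np.random.default_rng(0).normal(size=(50, 4))
    with pytest.raises(np.linalg.LinAlgError, match="condition number"):
        ml_discrepancy(biv_spec, theta, y.mean(axis=0), np.cov(y, rowvar=False))


# ---------------------------------------------------------------------------
# fit_ml
# ---------------------------------------------------------------------------

def test_saturated_fit_recovers_sample_moments(toy_bivariate_data):
    spec = saturated_spec(["x1", "x2"])
    fit = fit_ml(spec, toy_bivariate_data)
    y = toy_bivariate_data.to_numpy()
    S = np.cov(y, rowvar=False, ddof=1)
    assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
    assert fit.df == 0
    assert fit.estimates["mu[x1]"] == pytest.approx(y[:, 0].mean(), abs=1e-8)
    assert fit.estimates["var[x1]"] == pytest.approx(S[0, 0], abs=1e-7)
    assert fit.estimates["cov[x1,x2]"] == pytest.approx(S[0, 1], abs=1e-7)


def test_just_identified_fit_equals_difference_score_regression(small_cohort, biv_spec):
    """Oracle equivalence: the 14-parameter bivariate LCS has exactly as
    many parameters as sample moments, so ML equals the closed-form
    multivariate regression of observed changes on the baselines."""
    fit = fit_ml(biv_spec, small_cohort)
    oracle = difference_score_regression(small_cohort)
    assert fit.converged
    assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
    for k, v in oracle.items():
        assert fit.estimates[k] == pytest.approx(v, abs=1e-6), k


def test_optimizer_never_worse_than_closed_form(small_cohort, biv_spec):
    y = small_cohort[VOLUME_COLS].to_numpy()
    mean, S = y.mean(axis=0), np.cov(y, rowvar=False, ddof=1)
    start = closed_form_start(biv_spec, mean, S)
    f_start = ml_discrepancy(biv_spec, start, mean, S)
    fit = fit_ml(biv_spec, small_cohort)
    f_fit = ml_discrepancy(biv_spec, fit.estimates, mean, S)
    assert f_fit <= f_start + 1e-12


def test_sign_convention_covariance(small_cohort):
    """Flipping the change-score convention negates couplings and
    intercepts but leaves the log-likelihood unchanged."""
    pos = fit_ml(bivariate_lcs_spec(atrophy_positive=True), small_cohort)
    neg = fit_ml(bivariate_lcs_spec(atrophy_positive=False), small_cohort)
    assert neg.loglik == pytest.approx(pos.loglik, rel=1e-9)
    for label in ("gamma_t_dh", "gamma_h_dt", "beta_t", "beta_h",
                  "alpha_thal", "alpha_hipp"):
        assert neg.estimates[label] == pytest.approx(-pos.estimates[label], abs=1e-6)
    for label in ("phi_ht", "rho_ht", "psi_thal", "psi_hipp"):
        assert neg.estimates[label] == pytest.approx(pos.estimates[label], abs=1e-6)


def test_under_identified_spec_rejected(toy_bivariate_data):
    spec = saturated_spec(["x1", "x2"])
    extra = spec.params + (Parameter("covariance", "x1", "x2", "dup", 0.0),)
    bad = LCSModelSpec(observed=spec.observed, params=extra)
    with pytest.raises(ValueError, match="under-identified"):
        fit_ml(bad, toy_bivariate_data)


def test_too_few_cases_rejected(biv_spec, small_cohort):
    with pytest.raises(ValueError, match="too few complete cases"):
        fit_ml(biv_spec, small_cohort.head(5))


# ---------------------------------------------------------------------------
# FIML
# ---------------------------------------------------------------------------

def test_fiml_reduces_to_ml_on_complete_data(small_cohort, biv_spec):
    ml = fit_ml(biv_spec, small_cohort)
    fiml = fit_fiml(biv_spec, small_cohort)
    assert fiml.missing_method == "fiml"
    assert fiml.loglik == pytest.approx(ml.loglik, rel=1e-8)
    for k in biv_spec.labels:
        assert fiml.estimates[k] == pytest.approx(ml.estimates[k], rel=1e-8, abs=1e-12)


def test_fiml_two_pattern_loglik_matches_marginal_densities():
    """Casewise likelihood equals the sum of full and marginal Gaussian
    log-densities assembled by hand for a two-pattern toy."""
    rng = np.random.default_rng(5)
    full = rng.multivariate_normal([0.0, 1.0], [[1.0, 0.4], [0.4, 2.0]], size=30)
    data = pd.DataFrame(full, columns=["x1", "x2"])
    data.loc[15:, "x2"] = np.nan
    spec = saturated_spec(["x1", "x2"])
    theta = {"mu[x1]": 0.1, "mu[x2]": 0.9, "var[x1]": 1.1,
             "var[x2]": 1.8, "cov[x1,x2]": 0.3}
    fit = fit_fiml(spec, data, compute_se=False, compute_chi_square=False)
    # evaluate the engine's objective at a fixed theta against scipy
    nll = fit.objective(spec.theta_array(theta))
    both = data.dropna().to_numpy()
    only1 = data.loc[data.x2.isna(), "x1"].to_numpy()
    expect = (
        multivariate_normal([0.1, 0.9], [[1.1, 0.3], [0.3, 1.8]]).logpdf(both).sum()
        + multivariate_normal([0.1], [[1.1]]).logpdf(only1[:, None]).sum()
    )
    assert -nll == pytest.approx(expect, rel=1e-10)


def test_fiml_estimates_near_complete_case_truth(biv_spec):
    from deltalcs import MissingnessSpec, apply_missingness

    full = generate_longitudinal(bivariate_config(seed=99), 2000)
    masked = apply_missingness(full, MissingnessSpec(rate=0.5, seed=100))
    fit = fit_fiml(biv_spec, masked, compute_se=False)
    assert fit.converged
    assert fit.n_used == 2000
    assert fit.estimates["gamma_t_dh"] == pytest.approx(-0.048, abs=0.03)


def test_fiml_rejects_empty_rows_and_columns(biv_spec, small_cohort):
    bad = small_cohort.copy()
    bad.loc[0, VOLUME_COLS] = np.nan
    with pytest.raises(ValueError, match="no observed variables"):
        fit_fiml(biv_spec, bad)
    bad2 = small_cohort.copy()
    bad2["thal_t2_ml"] = np.nan
    with pytest.raises(ValueError, match="missing in every row"):
        fit_fiml(biv_spec, bad2)


# ---------------------------------------------------------------------------
# multigroup
# ---------------------------------------------------------------------------

def test_two_identical_groups_match_single_fit(small_cohort, biv_spec):
    doubled = pd.concat([small_cohort.assign(group="a"),
                         small_cohort.assign(group="b")], ignore_index=True)
    mg = fit_multigroup(biv_spec, doubled, "group")
    single = fit_ml(biv_spec, small_cohort)
    for g in ("a", "b"):
        for k in biv_spec.labels:
            assert mg.per_group[g].estimates[k] == pytest.approx(
                single.estimates[k], rel=1e-8, abs=1e-10)


def test_full_equality_constraints_match_pooled_moments(biv_spec):
    """Constraining everything equal across groups reproduces the fit to
    the n-weighted pooled within-group moments."""
    a = generate_longitudinal(bivariate_config(seed=50), 300).assign(group="a")
    b = generate_longitudinal(bivariate_config(seed=51), 400).assign(group="b")
    both = pd.concat([a, b], ignore_index=True)
    mg = fit_multigroup(biv_spec, both, "group",
                        equality_constraints=biv_spec.labels, compute_se=False)
    assert mg.converged

    # oracle: minimize the pooled discrepancy sum directly over theta via
    # the per-group moments and a dense grid-free optimum = the joint fit;
    # instead verify stationarity by comparing against a stacked refit
    # whose groups share all moments (single-group fit on concatenated
    # data reproduces the estimates up to between-group mean variation)
    y_a = a[VOLUME_COLS].to_numpy()
    y_b = b[VOLUME_COLS].to_numpy()
    stats_g = [(len(y), y.mean(axis=0), np.cov(y, rowvar=False, ddof=1))
               for y in (y_a, y_b)]

    def pooled_objective(vec):
        return sum((n_g - 1) * ml_discrepancy(biv_spec, vec, m_g, S_g)
                   for n_g, m_g, S_g in stats_g)

    theta_hat = biv_spec.theta_array(mg.per_group["a"].estimates)
    f_hat = pooled_objective(theta_hat)
    rng = np.random.default_rng(0)
    for _ in range(20):  # no perturbation improves the pooled objective
        bump = theta_hat * (1 + rng.normal(scale=1e-3, size=len(theta_hat)))
        assert pooled_objective(bump) >= f_hat - 1e-9


def test_multigroup_rejects_missing_group(biv_spec, small_cohort):
    with pytest.raises(ValueError, match="group column"):
        fit_multigroup(biv_spec, small_cohort, "no_such_column")
    with pytest.raises(ValueError, match="unknown labels"):
        fit_multigroup(biv_spec, small_cohort.assign(group="x"), "group",
                       equality_constraints=["nope"])


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def test_ses_nonnegative_or_flagged(small_cohort, biv_spec):
    fit = fit_ml(biv_spec, small_cohort)
    for k, se in fit.ses.items():
        assert np.isnan(se) or se >= 0, k


def test_saturated_variance_se_matches_closed_form():
    """Normal-theory closed form: SE(sigma^2) ~ sigma^2 * sqrt(2/n)."""
    rng = np.random.default_rng(8)
    n = 2000
    data = pd.DataFrame({"x": rng.normal(3.0, 1.7, n)})
    fit = fit_ml(saturated_spec(["x"]), data)
    var_hat = fit.estimates["var[x]"]
    assert fit.ses["var[x]"] == pytest.approx(var_hat * np.sqrt(2 / n), rel=0.05)


def test_standard_errors_requires_context(biv_spec):
    from deltalcs import FitResult

    bare = FitResult(estimates={"a": 1.0}, ses={}, pvalues={}, loglik=0.0,
                     chi_square=0.0, df=0, n_used=10, converged=True,
                     missing_method="complete")
    with pytest.raises(ValueError, match="information"):
        standard_errors(bare)


def test_tidy_export_schema(small_cohort, biv_spec):
    frame = fit_ml(biv_spec, small_cohort).to_frame()
    assert list(frame.columns) == ["label", "estimate", "se", "z", "p", "group"]
    assert len(frame) == biv_spec.n_free
    assert frame["p"].between(0, 1).all()
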