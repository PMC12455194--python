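"""Selection-bias sensitivity machinery.

Propensity scores come from a logistic regression fitted by IRLS;
matching is greedy 1:1 nearest-neighbour without replacement under a
caliper on the probability scale.  Multiple imputation uses predictive
mean matching (PMM): per imputation a Bayesian draw of the linear-model
parameters produces predictions, and each missing cell is filled with
the observed value of one of its k nearest donors by predicted value.
Imputed analyses are pooled by Rubin's rules with Barnard-Rubin
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchResult",
    "ImputationSet",
    "PooledEstimate",
    "estimate_propensity",
    "match_nearest",
    "impute_pmm",
    "pool_rubin",
    "attrition_table",
]


@dataclass
class MatchResult:
    pairs: list[tuple]              # (smaller-group id, larger-group id)
    scores: pd.Series
    caliper: float
    match_rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])


@dataclass
class ImputationSet:
    tables: list[pd.DataFrame]
    k_donors: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.tables)


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    se: float
    df: float
    p: float
    within_var: float
    between_var: float
    total_var: float
    m: int


def estimate_propensity(
    table: pd.DataFrame,
    covariates: Sequence[str],
    membership_column: str,
) -> pd.Series:
    """Per-row propensity of membership from a logistic model fitted by
    iteratively reweighted least squares."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)

    cols = list(covariates) + [membership_column]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    rows = table[cols].dropna()
    y = rows[membership_column].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0} or len(np.unique(y)) < 2:
        raise ValueError("membership column must be binary with both levels present")
    if covariates:
        X = sm.add_constant(rows[list(covariates)].to_numpy(dtype=float))
    else:  # prevalence-only model
        X = np.ones((len(rows), 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except (PerfectSeparationError, PerfectSeparationWarning) as err:
        raise ValueError(f"propensity model failed (possible complete separation): {err}")
    scores = pd.Series(np.nan, index=table.index, name="propensity", dtype=float)
    scores.loc[rows.index] = res.predict(X)
    return scores


def match_nearest(
    scores: pd.Series,
    membership: pd.Series,
    caliper: float = 0.001,
    order: str = "descending",
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    The smaller group is traversed in ``order`` of its propensity
    scores ('descending', 'ascending' or 'random'); each member takes
    the nearest unused score in the larger group, and the pair is kept
    only if the absolute score difference is within the caliper.
    """
    if caliper < 0:
        raise ValueError("caliper must be >= 0")
    ok = scores.notna() & membership.notna()
    s = scores[ok]
    m = membership[ok].astype(bool)
    g1 = s[m]
    g0 = s[~m]
    if g1.empty or g0.empty:
        raise ValueError("both groups must be non-empty")
    small, large = (g1, g0) if len(g1) <= len(g0) else (g0, g1)
    rng = np.random.default_rng(seed)
    if order == "descending":
        seq = small.sort_values(ascending=False, kind="mergesort").index
    elif order == "ascending":
        seq = small.sort_values(kind="mergesort").index
    elif order == "random":
        seq = small.index[rng.permutation(len(small))]
    else:
        raise ValueError(f"unknown order {order!r}")

    avail_idx = np.array(large.index)
    avail_val = large.to_numpy(dtype=float)
    used = np.zeros(len(avail_idx), dtype=bool)
    pairs: list[tuple] = []
    for i in seq:
        free = np.flatnonzero(~used)
        if free.size == 0:
            break
        d = np.abs(avail_val[free] - small[i])
        j = free[np.argmin(d)]
        if abs(avail_val[j] - small[i]) <= caliper:
            used[j] = True
            pairs.append((i, avail_idx[j]))
    return MatchResult(
        pairs=pairs,
        scores=scores,
        caliper=caliper,
        match_rate=len(pairs) / len(small),
    )


def _pmm_one_column(rows, target, predictors, k, rng):
    obs = rows.dropna(subset=[target] + predictors)
    mis = rows[rows[target].isna()].dropna(subset=predictors)
    if mis.empty:
        return {}
    n_obs, p = len(obs), len(predictors) + 1
    if n_obs <= p:
        raise ValueError(
            f"only {n_obs} observed rows for {p} imputation-model parameters of {target!r}")
    X = np.column_stack([np.ones(n_obs)] +
                        [obs[c].to_numpy(dtype=float) for c in predictors])
    y = obs[target].to_numpy(dtype=float)
    XtX = X.T @ X
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = n_obs - p
    # normal-inverse-gamma posterior draw
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta_hat, cov)
    yhat_obs = X @ beta_hat
    Xm = np.column_stack([np.ones(len(mis))] +
                         [mis[c].to_numpy(dtype=float) for c in predictors])
    yhat_mis = Xm @ beta_star
    fills = {}
    kk = min(k, n_obs)
    for row_i, pred in zip(mis.index, yhat_mis):
        d = np.abs(yhat_obs - pred)
        donors = np.argpartition(d, kk - 1)[:kk]
        fills[row_i] = y[donors[rng.integers(kk)]]
    return fills


def impute_pmm(
    table: pd.DataFrame,
    target_columns: Sequence[str],
    predictors: Sequence[str],
    m: int = 40,
    k_donors: int = 5,
    seed: int = 0,
) -> ImputationSet:
    """Predictive-mean-matching multiple imputation.

    Every imputed value is an observed donor value of its column; cells
    observed in the input are never altered.  Imputation ``i`` uses the
    base seed plus ``i`` for its parameter draw and donor choices.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    missing = [c for c in list(target_columns) + list(predictors)
               if c not in table.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    tables = []
    for i in range(m):
        rng = np.random.default_rng(seed + i)
        filled = table.copy()
        for target in target_columns:
            for row_i, value in _pmm_one_column(
                    table, target, list(predictors), k_donors, rng).items():
                filled.loc[row_i, target] = value
        tables.append(filled)
    return ImputationSet(tables=tables, k_donors=k_donors, seed=seed)


def pool_rubin(
    estimates_per_imputation,
    variances_per_imputation,
    dfcom: float = np.inf,
) -> PooledEstimate:
    """Rubin's rules: pooled estimate, total variance W + (1+1/m)B, and
    Barnard-Rubin degrees of freedom (``dfcom`` = complete-data df)."""
    q = np.asarray(estimates_per_imputation, dtype=float)
    u = np.asarray(variances_per_imputation, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or len(q) < 1:
        raise ValueError("estimates and variances must be aligned 1-d arrays")
    m = len(q)
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1)) if m > 1 else 0.0
    T = W + (1 + 1 / m) * B
    if B == 0 or m == 1:
        df = np.inf if not np.isfinite(dfcom) else float(dfcom)
    else:
        lam = (1 + 1 / m) * B / T
        df_old = (m - 1) / lam**2
        if np.isfinite(dfcom):
            df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
            df = 1 / (1 / df_old + 1 / df_obs)
        else:
            df = df_old
    se = float(np.sqrt(T))
    if se > 0:
        tstat = qbar / se
        p = float(2 * (stats.t.sf(abs(tstat), df) if np.isfinite(df)
                       else stats.norm.sf(abs(tstat))))
    else:
        p = np.nan
    return PooledEstimate(estimate=qbar, se=se, df=float(df), p=p,
                          within_var=W, between_var=B, total_var=float(T), m=m)


def attrition_table(
    table: pd.DataFrame,
    retained_mask: pd.Series,
    covariates: Sequence[str],
) -> pd.DataFrame:
    """Compare covariate means between the full sample and the retained
    (longitudinal) subsample."""
    rows = []
    for c in covariates:
        full = table[c].astype(float)
        kept = table.loc[retained_mask, c].astype(float)
        rows.append({
            "covariate": c,
            "full_mean": full.mean(), "full_sd": full.std(ddof=1),
            "retained_mean": kept.mean(), "retained_sd": kept.std(ddof=1),
            "difference": kept.mean() - full.mean(),
        })
    return pd.DataFrame(rows)
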