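"""Cross-sectional linear models, collinearity screening, FDR control,
and the two-timepoint session test.

Formulas use a minimal text grammar ``outcome ~ a + b + c`` in which
every term is a numeric column; an intercept is always included.  OLS
is solved by QR with classical (homoskedastic) standard errors and
two-sided t p-values on n-k degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearFit",
    "SessionTest",
    "parse_formula",
    "fit_ols",
    "vif",
    "bh_fdr",
    "fit_session_lmm",
    "to_long_sessions",
]


@dataclass(frozen=True)
class LinearFit:
    outcome: str
    terms: tuple[str, ...]          # includes "intercept"
    coefficients: dict[str, float]
    ses: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    adj_r_squared: float
    resid_sd: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "estimate": [self.coefficients[t] for t in self.terms],
                "se": [self.ses[t] for t in self.terms],
                "t": [self.tvalues[t] for t in self.terms],
                "p": [self.pvalues[t] for t in self.terms],
            }
        )


@dataclass(frozen=True)
class SessionTest:
    """Fixed session effect from the random-intercept model
    volume ~ session + interval + (1 | participant)."""

    session_effect: float
    session_se: float
    session_t: float
    session_p: float
    interval_effect: float
    random_intercept_var: float
    residual_var: float
    n_participants: int
    n_dropped: int


def parse_formula(formula: str) -> tuple[str, list[str]]:
    if "~" not in formula:
        raise ValueError("formula must contain '~'")
    lhs, rhs = formula.split("~", 1)
    outcome = lhs.strip()
    terms = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
    if not outcome:
        raise ValueError("formula lacks an outcome")
    return outcome, terms


def _design(table: pd.DataFrame, outcome: str, terms: list[str]):
    cols = [outcome] + terms
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    rows = table[cols].dropna()
    y = rows[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(rows))] + [rows[t].to_numpy(dtype=float) for t in terms])
    return y, X, rows


def _check_rank(X: np.ndarray, names: list[str]):
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 1e2
    aliased = [names[i] for i in np.flatnonzero(diag < tol)]
    if aliased:
        raise ValueError(f"design is rank deficient; aliased terms: {aliased}")


def fit_ols(table: pd.DataFrame, formula: str) -> LinearFit:
    """Ordinary least squares for ``outcome ~ a + b + ...``."""
    outcome, terms = parse_formula(formula)
    y, X, _ = _design(table, outcome, terms)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} rows cannot identify {k} coefficients")
    names = ["intercept"] + terms
    _check_rank(X, names)
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    dof = n - k
    s2 = float(resid @ resid) / dof
    Rinv = np.linalg.solve(R, np.eye(k))
    cov = s2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    tval = beta / se
    pval = 2 * stats.t.sf(np.abs(tval), dof)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(resid @ resid)
    r2 = 1 - rss / tss if tss > 0 else 1.0
    adj = 1 - (1 - r2) * (n - 1) / dof
    return LinearFit(
        outcome=outcome,
        terms=tuple(names),
        coefficients=dict(zip(names, beta)),
        ses=dict(zip(names, se)),
        tvalues=dict(zip(names, tval)),
        pvalues=dict(zip(names, pval)),
        r_squared=r2,
        adj_r_squared=adj,
        resid_sd=float(np.sqrt(s2)),
        n=n,
    )


def vif(table: pd.DataFrame, terms: list[str], threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors 1/(1-R2_j); perfect collinearity is
    reported as infinite.  Terms above ``threshold`` are flagged."""
    out = []
    for t in terms:
        others = [o for o in terms if o != t]
        if not others:
            out.append((t, 1.0, False))
            continue
        try:
            fit = fit_ols(table, f"{t} ~ {' + '.join(others)}")
            r2 = min(fit.r_squared, 1.0)
        except ValueError:
            r2 = 1.0
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append((t, v, v > threshold))
    return pd.DataFrame(out, columns=["term", "vif", "flagged"])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def to_long_sessions(
    table: pd.DataFrame,
    baseline_col: str,
    followup_col: str,
    id_col: str = "participant_id",
    interval_col: str = "interval_y",
) -> pd.DataFrame:
    """Stack a wide two-timepoint table into one row per scan session."""
    if interval_col in table.columns and table[interval_col].notna().any():
        interval = table[interval_col]
    else:
        interval = pd.Series(0.0, index=table.index)
    long = pd.concat(
        [
            pd.DataFrame({
                id_col: table[id_col], "session": 0,
                "volume": table[baseline_col], "interval_y": interval,
            }),
            pd.DataFrame({
                id_col: table[id_col], "session": 1,
                "volume": table[followup_col], "interval_y": interval,
            }),
        ],
        ignore_index=True,
    )
    return long.dropna(subset=["volume"])


def fit_session_lmm(
    long_table: pd.DataFrame,
    id_col: str = "participant_id",
    volume_col: str = "volume",
    session_col: str = "session",
    interval_col: str = "interval_y",
) -> SessionTest:
    """REML random-intercept test for a volume difference between scan
    sessions, controlling the inter-scan interval.

    Participants without exactly one observation per session are dropped
    (with a warning carrying the count).  In this balanced two-timepoint
    design the session fixed effect equals the mean within-participant
    difference.
    """
    import statsmodels.formula.api as smf

    counts = long_table.groupby(id_col)[volume_col].count()
    keep = counts.index[counts == 2]
    n_dropped = int((counts != 2).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} unpaired participants", stacklevel=2)
    data = long_table[long_table[id_col].isin(keep)].copy()
    if data.empty:
        raise ValueError("no paired participants to fit")
    data = data.rename(columns={volume_col: "_vol", session_col: "_ses",
                                interval_col: "_int", id_col: "_id"})
    # a constant interval is collinear with the intercept and is dropped
    has_interval = data["_int"].nunique() > 1
    formula = "_vol ~ _ses + _int" if has_interval else "_vol ~ _ses"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["_id"])
        res = model.fit(reml=True, method="lbfgs")
    return SessionTest(
        session_effect=float(res.params["_ses"]),
        session_se=float(res.bse["_ses"]),
        session_t=float(res.tvalues["_ses"]),
        session_p=float(res.pvalues["_ses"]),
        interval_effect=float(res.params["_int"]) if has_interval else np.nan,
        random_intercept_var=float(res.cov_re.iloc[0, 0]),
        residual_var=float(res.scale),
        n_participants=int(len(keep)),
        n_dropped=n_dropped,
    )
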