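"""Structural-equation engine for latent change score (LCS) models.

An LCS model treats the follow-up measurement of each variable as the
baseline minus a latent change (atrophy-positive convention), with the
loadings of baseline and change on the follow-up fixed to +1/-1.  The
latent changes are then regressed on baseline levels (self-feedback
``beta``) and on the other variable's baseline (cross-coupling
``gamma``), with freely correlated residuals.

Internally every model is held in a reticular-action (RAM) form over
the joint vector of observed and latent variables::

    v = m + A v + zeta,   Cov(zeta) = S
    mu = (I - A)^{-1} m,  Sigma = (I - A)^{-1} S (I - A)^{-T}

with the observed sub-vector selected for the likelihood.  Fixed unit
loadings live in ``A``; free paths, covariances, variances, means and
intercepts are labelled parameters.  The same machinery covers the
bivariate model, the age-augmented multivariate model and multigroup
(sex-stratified) fits.

Estimation minimises the normal-theory maximum-likelihood discrepancy

    F = ln|Sigma| + tr(S Sigma^-1) + (m - mu)' Sigma^-1 (m - mu)
        - ln|S| - p

from a closed-form start (multivariate regression of observed
difference scores on the baselines), so that every just-identified
model is solved essentially exactly.  Missing data are handled by
full-information maximum likelihood (FIML): each row contributes the
marginal Gaussian density over its observed subset, with rows grouped
by missingness pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Parameter",
    "LCSModelSpec",
    "FitResult",
    "bivariate_lcs_spec",
    "multivariate_age_spec",
    "saturated_spec",
    "implied_moments",
    "ml_discrepancy",
    "fit_ml",
    "fit_fiml",
    "fit_multigroup",
    "standard_errors",
    "closed_form_start",
]

PARAM_KINDS = ("path", "covariance", "variance", "mean", "intercept")

_PD_PENALTY = 1e10
_GRAD_TOL = 1e-8
_MAX_ITER = 500


@dataclass(frozen=True)
class Parameter:
    """One free parameter of an LCS model.

    ``kind`` is one of ``path`` (directed src -> dst), ``covariance``
    (undirected src ~~ dst), ``variance`` (src ~~ src), ``mean``
    (exogenous mean) or ``intercept`` (endogenous intercept); the last
    two differ only in name.  ``start`` seeds the optimizer when no
    closed-form value is available.
    """

    kind: str
    src: str
    dst: str
    label: str
    start: float = 0.0

    def __post_init__(self):
        if self.kind not in PARAM_KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")


@dataclass(frozen=True)
class LCSModelSpec:
    """Declarative description of an LCS structural model.

    ``fixed_paths`` carry the unit loadings that define each latent
    change (follow-up = baseline - change); their values must be
    exactly +1 or -1.
    """

    observed: tuple[str, ...]
    latent: tuple[str, ...] = ()
    fixed_paths: tuple[tuple[str, str, float], ...] = ()
    params: tuple[Parameter, ...] = ()

    def __post_init__(self):
        names = self.observed + self.latent
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        declared = set(names)
        for src, dst, val in self.fixed_paths:
            if src not in declared or dst not in declared:
                raise ValueError(f"fixed path {src}->{dst} references undeclared variable")
            if val not in (1.0, -1.0, 1, -1):
                raise ValueError(f"fixed loading {src}->{dst} must be +1 or -1, got {val}")
        labels = [p.label for p in self.params]
        if len(set(labels)) != len(labels):
            raise ValueError("parameter labels must be unique")
        for p in self.params:
            if p.src not in declared or p.dst not in declared:
                raise ValueError(f"parameter {p.label} references undeclared variable")

    # -- bookkeeping -------------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.params)

    @property
    def n_free(self) -> int:
        return len(self.params)

    @property
    def n_moments(self) -> int:
        p = len(self.observed)
        return p + p * (p + 1) // 2

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    def theta_array(self, theta: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Coerce a dict or sequence of parameter values to spec order."""
        if isinstance(theta, Mapping):
            missing = [l for l in self.labels if l not in theta]
            if missing:
                raise ValueError(f"theta incomplete, missing {missing}")
            arr = np.array([float(theta[l]) for l in self.labels])
        else:
            arr = np.asarray(theta, dtype=float)
            if arr.shape != (self.n_free,):
                raise ValueError(f"theta has shape {arr.shape}, expected ({self.n_free},)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("theta contains non-finite values")
        return arr

    def theta_dict(self, arr: np.ndarray) -> dict[str, float]:
        return dict(zip(self.labels, np.asarray(arr, dtype=float)))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "observed": list(self.observed),
                "latent": list(self.latent),
                "fixed_paths": [list(fp) for fp in self.fixed_paths],
                "params": [
                    {"kind": p.kind, "src": p.src, "dst": p.dst,
                     "label": p.label, "start": p.start}
                    for p in self.params
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LCSModelSpec":
        d = json.loads(text)
        return cls(
            observed=tuple(d["observed"]),
            latent=tuple(d.get("latent", ())),
            fixed_paths=tuple((s, t, float(v)) for s, t, v in d.get("fixed_paths", ())),
            params=tuple(Parameter(**p) for p in d.get("params", ())),
        )


@dataclass
class FitResult:
    """Parameter estimates and inference for one fitted LCS model."""

    estimates: dict[str, float]
    ses: dict[str, float]
    pvalues: dict[str, float]
    loglik: float
    chi_square: float
    df: int
    n_used: int
    converged: bool
    missing_method: str
    per_group: dict[str, "FitResult"] | None = None
    spec: LCSModelSpec | None = field(default=None, repr=False)
    theta: np.ndarray | None = field(default=None, repr=False)
    objective: Callable[[np.ndarray], float] | None = field(default=None, repr=False)
    information: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)

    def zvalues(self) -> dict[str, float]:
        return {
            k: self.estimates[k] / self.ses[k] if self.ses.get(k, np.nan) > 0 else np.nan
            for k in self.estimates
        }

    def to_frame(self, group: str = "") -> pd.DataFrame:
        """Tidy export: label, estimate, se, z, p, group."""
        if self.per_group:
            return pd.concat(
                [sub.to_frame(group=g) for g, sub in self.per_group.items()],
                ignore_index=True,
            )
        z = self.zvalues()
        return pd.DataFrame(
            {
                "label": list(self.estimates),
                "estimate": [self.estimates[k] for k in self.estimates],
                "se": [self.ses.get(k, np.nan) for k in self.estimates],
                "z": [z[k] for k in self.estimates],
                "p": [self.pvalues.get(k, np.nan) for k in self.estimates],
                "group": group,
            }
        )


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def bivariate_lcs_spec(
    thal: tuple[str, str] = ("thal_t1_ml", "thal_t2_ml"),
    hipp: tuple[str, str] = ("hipp_t1_ml", "hipp_t2_ml"),
    atrophy_positive: bool = True,
) -> LCSModelSpec:
    """Two-variable LCS: latent thalamic and hippocampal change.

    With ``atrophy_positive`` (default) the follow-up loads on the
    change with -1, so a positive latent change is volume loss.
    """
    t1, t2 = thal
    h1, h2 = hipp
    load = -1.0 if atrophy_positive else 1.0
    return LCSModelSpec(
        observed=(t1, t2, h1, h2),
        latent=("d_thal", "d_hipp"),
        fixed_paths=(
            (t1, t2, 1.0), ("d_thal", t2, load),
            (h1, h2, 1.0), ("d_hipp", h2, load),
        ),
        params=(
            Parameter("mean", t1, t1, "mu_thal", 15.0),
            Parameter("mean", h1, h1, "mu_hipp", 7.5),
            Parameter("variance", t1, t1, "var_thal", 1.5),
            Parameter("variance", h1, h1, "var_hipp", 0.7),
            Parameter("covariance", t1, h1, "phi_ht", 0.5),
            Parameter("intercept", "d_thal", "d_thal", "alpha_thal", 0.0),
            Parameter("intercept", "d_hipp", "d_hipp", "alpha_hipp", 0.0),
            Parameter("path", t1, "d_thal", "beta_t", 0.0),
            Parameter("path", h1, "d_thal", "gamma_h_dt", 0.0),
            Parameter("path", h1, "d_hipp", "beta_h", 0.0),
            Parameter("path", t1, "d_hipp", "gamma_t_dh", 0.0),
            Parameter("variance", "d_thal", "d_thal", "psi_thal", 0.05),
            Parameter("variance", "d_hipp", "d_hipp", "psi_hipp", 0.05),
            Parameter("covariance", "d_thal", "d_hipp", "rho_ht", 0.0),
        ),
    )


def multivariate_age_spec(
    thal: tuple[str, str] = ("thal_t1_ml", "thal_t2_ml"),
    hipp: tuple[str, str] = ("hipp_t1_ml", "hipp_t2_ml"),
    age: str = "age_y",
    atrophy_positive: bool = True,
) -> LCSModelSpec:
    """Bivariate LCS with baseline age as an exogenous predictor of both
    latent changes (couplings ``gamma_age_dh``/``gamma_age_dt``) and free
    covariances with both baselines."""
    base = bivariate_lcs_spec(thal, hipp, atrophy_positive)
    t1 = thal[0]
    h1 = hipp[0]
    extra = (
        Parameter("mean", age, age, "mu_age", 68.0),
        Parameter("variance", age, age, "var_age", 20.0),
        Parameter("covariance", t1, age, "phi_t_age", 0.0),
        Parameter("covariance", h1, age, "phi_h_age", 0.0),
        Parameter("path", age, "d_hipp", "gamma_age_dh", 0.0),
        Parameter("path", age, "d_thal", "gamma_age_dt", 0.0),
    )
    return LCSModelSpec(
        observed=base.observed + (age,),
        latent=base.latent,
        fixed_paths=base.fixed_paths,
        params=base.params + extra,
    )


def saturated_spec(variables: Sequence[str]) -> LCSModelSpec:
    """All first and second moments free; fits any data perfectly."""
    variables = tuple(variables)
    params: list[Parameter] = []
    for v in variables:
        params.append(Parameter("mean", v, v, f"mu[{v}]", 0.0))
    for i, v in enumerate(variables):
        params.append(Parameter("variance", v, v, f"var[{v}]", 1.0))
        for w in variables[i + 1:]:
            params.append(Parameter("covariance", v, w, f"cov[{v},{w}]", 0.0))
    return LCSModelSpec(observed=variables, params=tuple(params))


# ---------------------------------------------------------------------------
# implied moments and discrepancy
# ---------------------------------------------------------------------------

def _ram_matrices(spec: LCSModelSpec, theta: np.ndarray):
    names = spec.observed + spec.latent
    idx = {v: i for i, v in enumerate(names)}
    nv = len(names)
    A = np.zeros((nv, nv))
    S = np.zeros((nv, nv))
    m = np.zeros(nv)
    for src, dst, val in spec.fixed_paths:
        A[idx[dst], idx[src]] = val
    for p, val in zip(spec.params, theta):
        i, j = idx[p.src], idx[p.dst]
        if p.kind == "path":
            A[j, i] = val
        elif p.kind in ("variance", "covariance"):
            S[i, j] = val
            S[j, i] = val
        else:  # mean / intercept
            m[i] = val
    return A, S, m, idx


def implied_moments(
    spec: LCSModelSpec, theta: Mapping[str, float] | Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix over
    ``spec.observed``, obtained by substituting the latent changes out
    of the structural equations."""
    arr = spec.theta_array(theta)
    A, S, m, _ = _ram_matrices(spec, arr)
    nv = A.shape[0]
    inv = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
    mu_all = inv @ m
    sig_all = inv @ S @ inv.T
    p = len(spec.observed)
    return mu_all[:p], sig_all[:p, :p]


def ml_discrepancy(
    spec: LCSModelSpec,
    theta: Mapping[str, float] | Sequence[float],
    sample_mean: np.ndarray,
    sample_cov: np.ndarray,
    n: int | None = None,
) -> float:
    """Normal-theory ML discrepancy between sample and implied moments.

    F >= 0 with equality iff the implied moments reproduce the sample
    moments exactly.  ``n`` is accepted for interface symmetry; the
    discrepancy itself does not depend on it.
    """
    sample_mean = np.asarray(sample_mean, dtype=float)
    sample_cov = np.asarray(sample_cov, dtype=float)
    p = len(spec.observed)
    sign_s, logdet_s = np.linalg.slogdet(sample_cov)
    if sign_s <= 0:
        raise ValueError("sample covariance must be positive definite")
    mu, sigma = implied_moments(spec, theta)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        cond = np.linalg.cond(sigma)
        raise np.linalg.LinAlgError(
            f"implied covariance is singular or indefinite (condition number {cond:.3g})"
        )
    sig_inv = np.linalg.solve(sigma, np.eye(p))
    diff = sample_mean - mu
    return float(
        logdet + np.trace(sample_cov @ sig_inv) + diff @ sig_inv @ diff - logdet_s - p
    )


def _gaussian_loglik(mu, sigma, sample_mean, sample_cov_n, n):
    """Exact multivariate-normal log-likelihood from sufficient statistics
    (``sample_cov_n`` uses the 1/n denominator)."""
    p = len(mu)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -np.inf
    sig_inv = np.linalg.solve(sigma, np.eye(p))
    diff = sample_mean - mu
    return -0.5 * n * (
        p * np.log(2 * np.pi) + logdet
        + np.trace(sample_cov_n @ sig_inv) + diff @ sig_inv @ diff
    )


# ---------------------------------------------------------------------------
# closed-form start (difference-score regression)
# ---------------------------------------------------------------------------

def _change_definitions(spec: LCSModelSpec):
    """Map each latent change to (baseline, follow-up, loading) from the
    fixed unit loadings, and list the exogenous observed variables."""
    into: dict[str, list[tuple[str, float]]] = {}
    endo_obs = set()
    for src, dst, val in spec.fixed_paths:
        if dst in spec.observed:
            into.setdefault(dst, []).append((src, val))
            endo_obs.add(dst)
    changes = {}
    for f, incoming in into.items():
        base = [s for s, v in incoming if s in spec.observed]
        lat = [(s, v) for s, v in incoming if s in spec.latent]
        if len(base) == 1 and len(lat) == 1:
            changes[lat[0][0]] = (base[0], f, lat[0][1])
    exog = [v for v in spec.observed if v not in endo_obs]
    return changes, exog


def closed_form_start(
    spec: LCSModelSpec, sample_mean: np.ndarray, sample_cov: np.ndarray
) -> dict[str, float]:
    """Parameter values from the observed-difference-score regression.

    Each latent change equals (follow-up - baseline)/loading, a linear
    function of the observed vector, so its moments follow from the
    sample moments.  Regressing each change on its declared predictors
    gives paths and intercepts; the residual (co)variances complete the
    solution.  For every just-identified LCS model this IS the ML
    solution; otherwise it is a high-quality start.
    """
    sample_mean = np.asarray(sample_mean, dtype=float)
    sample_cov = np.asarray(sample_cov, dtype=float)
    changes, exog = _change_definitions(spec)
    order = list(exog) + list(changes)
    obs_idx = {v: i for i, v in enumerate(spec.observed)}
    L = np.zeros((len(order), len(spec.observed)))
    for r, v in enumerate(order):
        if v in changes:
            b, f, s = changes[v]
            L[r, obs_idx[f]] = 1.0 / s
            L[r, obs_idx[b]] = -1.0 / s
        else:
            L[r, obs_idx[v]] = 1.0
    mean_t = L @ sample_mean
    cov_t = L @ sample_cov @ L.T
    tidx = {v: i for i, v in enumerate(order)}

    regressors = {d: [] for d in changes}
    for p in spec.params:
        if p.kind == "path" and p.dst in changes:
            regressors[p.dst].append(p.src)

    coefs: dict[str, dict[str, float]] = {}
    intercepts: dict[str, float] = {}
    for d, regs in regressors.items():
        ri = [tidx[r] for r in regs]
        di = tidx[d]
        if ri:
            b = np.linalg.solve(cov_t[np.ix_(ri, ri)], cov_t[ri, di])
        else:
            b = np.zeros(0)
        coefs[d] = dict(zip(regs, b))
        intercepts[d] = mean_t[di] - b @ mean_t[ri]

    def resid_cov(d1: str, d2: str) -> float:
        r1 = [tidx[r] for r in regressors[d1]]
        r2 = [tidx[r] for r in regressors[d2]]
        b1 = np.array([coefs[d1][r] for r in regressors[d1]])
        b2 = np.array([coefs[d2][r] for r in regressors[d2]])
        i1, i2 = tidx[d1], tidx[d2]
        out = cov_t[i1, i2]
        if r1:
            out -= b1 @ cov_t[r1, i2]
        if r2:
            out -= cov_t[i1, r2] @ b2
        if r1 and r2:
            out += b1 @ cov_t[np.ix_(r1, r2)] @ b2
        return float(out)

    theta: dict[str, float] = {}
    for p in spec.params:
        if p.kind in ("mean", "intercept"):
            if p.src in tidx:
                theta[p.label] = (
                    intercepts[p.src] if p.src in changes else float(mean_t[tidx[p.src]])
                )
            else:
                theta[p.label] = p.start
        elif p.kind == "path":
            if p.dst in changes and p.src in coefs.get(p.dst, {}):
                theta[p.label] = float(coefs[p.dst][p.src])
            else:
                theta[p.label] = p.start
        elif p.kind == "variance":
            if p.src in changes:
                theta[p.label] = max(resid_cov(p.src, p.src), 1e-10)
            elif p.src in tidx:
                theta[p.label] = float(cov_t[tidx[p.src], tidx[p.src]])
            else:
                theta[p.label] = p.start
        else:  # covariance
            if p.src in changes and p.dst in changes:
                theta[p.label] = resid_cov(p.src, p.dst)
            elif p.src in tidx and p.dst in tidx:
                theta[p.label] = float(cov_t[tidx[p.src], tidx[p.dst]])
            else:
                theta[p.label] = p.start
    return theta


# ---------------------------------------------------------------------------
# optimization helpers
# ---------------------------------------------------------------------------

def _transform(spec: LCSModelSpec):
    """Unconstrained reparameterization: log for variances, identity
    otherwise.  Implied-covariance positive definiteness is enforced by a
    penalty; starts are at the closed-form solution so the boundary is
    not approached in practice."""
    is_var = np.array([p.kind == "variance" for p in spec.params])

    def pack(theta: np.ndarray) -> np.ndarray:
        z = theta.copy()
        z[is_var] = np.log(np.maximum(theta[is_var], 1e-12))
        return z

    def unpack(z: np.ndarray) -> np.ndarray:
        theta = z.copy()
        theta[is_var] = np.exp(np.clip(z[is_var], -50, 50))
        return theta

    return pack, unpack


def _minimize(spec, objective, theta0):
    pack, unpack = _transform(spec)

    def fun(z):
        try:
            return objective(unpack(z))
        except (np.linalg.LinAlgError, ValueError):
            return _PD_PENALTY

    res = optimize.minimize(
        fun, pack(theta0), method="BFGS",
        options={"gtol": _GRAD_TOL, "maxiter": _MAX_ITER},
    )
    theta_hat = unpack(res.x)
    f_hat = fun(res.x)
    f0 = objective(theta0)
    if f0 < f_hat:  # never return worse than the closed-form start
        theta_hat, f_hat = theta0, f0
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-4 or f_hat <= f0 + 1e-12)
    return theta_hat, f_hat, converged


def _wald_p(est: dict, ses: dict) -> dict:
    out = {}
    for k, v in est.items():
        se = ses.get(k, np.nan)
        out[k] = 2 * stats.norm.sf(abs(v / se)) if se and np.isfinite(se) and se > 0 else np.nan
    return out


def _moment_jacobians(spec: LCSModelSpec, theta: np.ndarray, rel_step=1e-6):
    """Central-difference derivatives of the implied mean vector and
    covariance matrix with respect to each free parameter."""
    k = len(theta)
    dmu, dsig = [], []
    for i in range(k):
        h = rel_step * max(1.0, abs(theta[i]))
        up = theta.copy(); up[i] += h
        dn = theta.copy(); dn[i] -= h
        mu_u, sig_u = implied_moments(spec, up)
        mu_d, sig_d = implied_moments(spec, dn)
        dmu.append((mu_u - mu_d) / (2 * h))
        dsig.append((sig_u - sig_d) / (2 * h))
    return dmu, dsig


def _information_complete(spec: LCSModelSpec, theta: np.ndarray, n: int) -> np.ndarray:
    """Gaussian information matrix of the moment-structure model at
    ``theta`` for a complete sample of size ``n``."""
    mu, sigma = implied_moments(spec, theta)
    sig_inv = np.linalg.solve(sigma, np.eye(len(mu)))
    dmu, dsig = _moment_jacobians(spec, theta)
    k = len(theta)
    I = np.empty((k, k))
    a = [sig_inv @ ds for ds in dsig]
    for i in range(k):
        for j in range(i, k):
            val = dmu[i] @ sig_inv @ dmu[j] + 0.5 * np.trace(a[i] @ a[j])
            I[i, j] = I[j, i] = n * val
    return I


def _information_patterns(spec: LCSModelSpec, theta: np.ndarray, patterns) -> np.ndarray:
    """FIML information: sum of per-missingness-pattern Gaussian
    information over each pattern's observed subset."""
    mu, sigma = implied_moments(spec, theta)
    dmu, dsig = _moment_jacobians(spec, theta)
    k = len(theta)
    I = np.zeros((k, k))
    for cols, n_p, _, _ in patterns.values():
        sub_inv = np.linalg.solve(sigma[np.ix_(cols, cols)], np.eye(len(cols)))
        a = [sub_inv @ ds[np.ix_(cols, cols)] for ds in dsig]
        for i in range(k):
            di = dmu[i][cols]
            for j in range(i, k):
                val = di @ sub_inv @ dmu[j][cols] + 0.5 * np.trace(a[i] @ a[j])
                I[i, j] += n_p * val
                if i != j:
                    I[j, i] += n_p * val
    return I


def _ses_from_information(I: np.ndarray, labels) -> dict[str, float]:
    try:
        cov = np.linalg.inv(I)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        return dict(zip(labels, np.sqrt(diag)))
    except np.linalg.LinAlgError:
        return {k: np.nan for k in labels}


def standard_errors(fit: FitResult, method: str = "observed_information") -> FitResult:
    """Standard errors from the inverse information matrix at the optimum.

    The information is assembled from numerically differentiated implied
    moments (the Gaussian moment-structure form); at the optimum of a
    just-identified model this equals the observed information exactly.
    A singular information matrix flags the SEs undefined; the fit
    itself is retained.
    """
    if method != "observed_information":
        raise ValueError(f"unknown SE method {method!r}")
    if fit.per_group is not None and fit.information is None:
        new_groups = {g: standard_errors(sub) for g, sub in fit.per_group.items()}
        ses = {}
        pv = {}
        for g, sub in new_groups.items():
            for k in sub.estimates:
                ses[f"{k}|{g}"] = sub.ses[k]
                pv[f"{k}|{g}"] = sub.pvalues[k]
        return replace(fit, per_group=new_groups, ses=ses, pvalues=pv)
    if fit.information is None or fit.theta is None:
        raise ValueError("fit does not carry an information matrix; cannot compute SEs")
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    I = fit.information(fit.theta)
    ses = _ses_from_information(I, list(fit.estimates))
    pvalues = _wald_p(fit.estimates, ses)
    return replace(fit, ses=ses, pvalues=pvalues)


# ---------------------------------------------------------------------------
# fitting: complete-data ML
# ---------------------------------------------------------------------------

def fit_ml(
    spec: LCSModelSpec,
    data: pd.DataFrame,
    compute_se: bool = True,
) -> FitResult:
    """Maximum-likelihood fit on complete cases.

    The sample covariance uses the n-1 denominator and the model
    chi-square is (n-1) * F_min; the reported log-likelihood is the
    exact casewise Gaussian log-likelihood at the optimum.
    """
    cols = list(spec.observed)
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks required columns {missing_cols}")
    rows = data[cols].dropna()
    n = len(rows)
    if n < max(spec.n_free, len(cols) + 1):
        raise ValueError(f"too few complete cases ({n}) to fit {spec.n_free} parameters")
    if spec.df < 0:
        raise ValueError(
            f"model is under-identified: {spec.n_free} free parameters for "
            f"{spec.n_moments} sample moments"
        )
    y = rows.to_numpy(dtype=float)
    mean = y.mean(axis=0)
    S = np.atleast_2d(np.cov(y, rowvar=False, ddof=1))
    Sn = S * (n - 1) / n

    def objective(theta):
        return ml_discrepancy(spec, theta, mean, S)

    start = closed_form_start(spec, mean, S)
    theta0 = spec.theta_array(start)
    theta_hat, f_min, converged = _minimize(spec, objective, theta0)
    chi2 = max((n - 1) * f_min, 0.0)
    mu, sigma = implied_moments(spec, theta_hat)
    ll = _gaussian_loglik(mu, sigma, mean, Sn, n)

    def negloglik(theta):
        mu_t, sig_t = implied_moments(spec, theta)
        return -_gaussian_loglik(mu_t, sig_t, mean, Sn, n)

    estimates = spec.theta_dict(theta_hat)
    fit = FitResult(
        estimates=estimates,
        ses={k: np.nan for k in estimates},
        pvalues={k: np.nan for k in estimates},
        loglik=float(ll),
        chi_square=float(chi2),
        df=spec.df,
        n_used=n,
        converged=converged,
        missing_method="complete",
        spec=spec,
        theta=theta_hat,
        objective=negloglik,
        information=lambda th: _information_complete(spec, th, n),
    )
    if compute_se and converged:
        fit = standard_errors(fit)
    return fit


# ---------------------------------------------------------------------------
# fitting: FIML
# ---------------------------------------------------------------------------

def _pattern_stats(y: np.ndarray):
    """Group rows by missingness pattern; per pattern return the observed
    column indices, case count, mean and within-pattern scatter."""
    obs = ~np.isnan(y)
    patterns = {}
    keys = [tuple(row) for row in obs]
    order = {}
    for i, k in enumerate(keys):
        order.setdefault(k, []).append(i)
    for k, rows in order.items():
        cols = np.flatnonzero(np.array(k))
        block = y[np.ix_(rows, cols)]
        n_p = len(rows)
        mean_p = block.mean(axis=0)
        dev = block - mean_p
        W = dev.T @ dev
        patterns[k] = (cols, n_p, mean_p, W)
    return patterns


def _fiml_negloglik_factory(spec: LCSModelSpec, patterns):
    log2pi = np.log(2 * np.pi)

    def negloglik(theta):
        mu, sigma = implied_moments(spec, theta)
        total = 0.0
        for cols, n_p, mean_p, W in patterns.values():
            sub = sigma[np.ix_(cols, cols)]
            sign, logdet = np.linalg.slogdet(sub)
            if sign <= 0:
                return _PD_PENALTY
            inv = np.linalg.solve(sub, np.eye(len(cols)))
            d = mean_p - mu[cols]
            total += 0.5 * (
                n_p * (len(cols) * log2pi + logdet)
                + n_p * d @ inv @ d + np.trace(inv @ W)
            )
        return total

    return negloglik


def _pairwise_moments(y: np.ndarray):
    """Available-case means and covariances, eigenvalue-clipped to PD."""
    p = y.shape[1]
    mean = np.nanmean(y, axis=0)
    cov = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ok = ~np.isnan(y[:, i]) & ~np.isnan(y[:, j])
            if ok.sum() < 3:
                raise ValueError("insufficient pairwise coverage for FIML start")
            xi = y[ok, i] - y[ok, i].mean()
            xj = y[ok, j] - y[ok, j].mean()
            cov[i, j] = cov[j, i] = (xi @ xj) / (ok.sum() - 1)
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w, 1e-6)
    return mean, (v * w) @ v.T


def fit_fiml(
    spec: LCSModelSpec,
    data: pd.DataFrame,
    compute_se: bool = True,
    compute_chi_square: bool = True,
) -> FitResult:
    """Full-information ML under missing-at-random follow-up data.

    Each row contributes the marginal multivariate-normal density over
    its observed subset, with rows grouped by missingness pattern.  With
    complete data this reduces exactly to :func:`fit_ml`.
    """
    cols = list(spec.observed)
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks required columns {missing_cols}")
    y = data[cols].to_numpy(dtype=float)
    obs = ~np.isnan(y)
    if np.any(~obs.any(axis=1)):
        raise ValueError("rows with no observed variables are not allowed")
    never = [cols[j] for j in range(len(cols)) if not obs[:, j].any()]
    if never:
        raise ValueError(f"variables missing in every row: {never}")
    if obs.all():
        fit = fit_ml(spec, data, compute_se=compute_se)
        return replace(fit, missing_method="fiml")

    patterns = _pattern_stats(y)
    negloglik = _fiml_negloglik_factory(spec, patterns)

    complete = data[cols].dropna()
    if len(complete) >= max(len(cols) + 2, spec.n_free):
        yc = complete.to_numpy(dtype=float)
        start = closed_form_start(
            spec, yc.mean(axis=0), np.cov(yc, rowvar=False, ddof=1)
        )
    else:
        mean_pw, cov_pw = _pairwise_moments(y)
        start = closed_form_start(spec, mean_pw, cov_pw)
    theta0 = spec.theta_array(start)
    theta_hat, nll, converged = _minimize(spec, negloglik, theta0)

    chi2 = np.nan
    if compute_chi_square:
        if spec.df == 0:
            chi2 = 0.0
        else:
            sat = saturated_spec(spec.observed)
            mean_pw, cov_pw = _pairwise_moments(y)
            sat0 = sat.theta_array(closed_form_start(sat, mean_pw, cov_pw))
            sat_nll = _fiml_negloglik_factory(sat, patterns)
            _, sat_min, _ = _minimize(sat, sat_nll, sat0)
            chi2 = max(2.0 * (nll - sat_min), 0.0)

    estimates = spec.theta_dict(theta_hat)
    fit = FitResult(
        estimates=estimates,
        ses={k: np.nan for k in estimates},
        pvalues={k: np.nan for k in estimates},
        loglik=float(-nll),
        chi_square=float(chi2),
        df=spec.df,
        n_used=int(len(y)),
        converged=converged,
        missing_method="fiml",
        spec=spec,
        theta=theta_hat,
        objective=negloglik,
        information=lambda th: _information_patterns(spec, th, patterns),
    )
    if compute_se and converged:
        fit = standard_errors(fit)
    return fit


# ---------------------------------------------------------------------------
# fitting: multigroup
# ---------------------------------------------------------------------------

def fit_multigroup(
    spec: LCSModelSpec,
    data: pd.DataFrame,
    group_column: str,
    equality_constraints: Iterable[str] = (),
    compute_se: bool = True,
) -> FitResult:
    """Multigroup fit with a joint likelihood summed over groups.

    By default every parameter is free per group (separable into
    independent single-group fits); labels listed in
    ``equality_constraints`` are constrained equal across groups.
    """
    if group_column not in data.columns:
        raise ValueError(f"group column {group_column!r} not in data")
    groups = [g for g in pd.unique(data[group_column]) if pd.notna(g)]
    if not groups:
        raise ValueError("no non-empty groups")
    shared = tuple(equality_constraints)
    unknown = [l for l in shared if l not in spec.labels]
    if unknown:
        raise ValueError(f"equality constraints reference unknown labels {unknown}")
    subsets = {g: data.loc[data[group_column] == g] for g in groups}
    for g, sub in subsets.items():
        if sub[list(spec.observed)].dropna().empty:
            raise ValueError(f"group {g!r} has no complete cases")

    if not shared:
        per_group = {str(g): fit_ml(spec, subsets[g], compute_se=compute_se) for g in groups}
        estimates, ses, pvalues = {}, {}, {}
        for g, sub in per_group.items():
            for k in sub.estimates:
                estimates[f"{k}|{g}"] = sub.estimates[k]
                ses[f"{k}|{g}"] = sub.ses[k]
                pvalues[f"{k}|{g}"] = sub.pvalues[k]
        return FitResult(
            estimates=estimates,
            ses=ses,
            pvalues=pvalues,
            loglik=float(sum(s.loglik for s in per_group.values())),
            chi_square=float(sum(s.chi_square for s in per_group.values())),
            df=int(sum(s.df for s in per_group.values())),
            n_used=int(sum(s.n_used for s in per_group.values())),
            converged=all(s.converged for s in per_group.values()),
            missing_method="complete",
            per_group=per_group,
        )

    # joint fit with equality constraints
    stats_by_group = {}
    starts = {}
    for g in groups:
        rows = subsets[g][list(spec.observed)].dropna().to_numpy(dtype=float)
        n_g = len(rows)
        mean_g = rows.mean(axis=0)
        S_g = np.cov(rows, rowvar=False, ddof=1)
        stats_by_group[g] = (n_g, mean_g, S_g, S_g * (n_g - 1) / n_g)
        starts[g] = closed_form_start(spec, mean_g, S_g)

    free_labels = [l for l in spec.labels if l not in shared]
    entries = [(l, None) for l in shared] + [(l, g) for g in groups for l in free_labels]
    pos = {e: i for i, e in enumerate(entries)}
    n_total = sum(stats_by_group[g][0] for g in groups)

    x0 = np.empty(len(entries))
    for l in shared:
        x0[pos[(l, None)]] = sum(
            stats_by_group[g][0] * starts[g][l] for g in groups
        ) / n_total
    for g in groups:
        for l in free_labels:
            x0[pos[(l, g)]] = starts[g][l]

    def theta_for(x, g):
        return np.array([
            x[pos[(l, None)]] if l in shared else x[pos[(l, g)]] for l in spec.labels
        ])

    def objective(x):
        total = 0.0
        for g in groups:
            n_g, mean_g, S_g, _ = stats_by_group[g]
            try:
                total += (n_g - 1) * ml_discrepancy(spec, theta_for(x, g), mean_g, S_g)
            except (np.linalg.LinAlgError, ValueError):
                return _PD_PENALTY
        return total

    kind_by_label = {p.label: p.kind for p in spec.params}
    is_var = np.array([kind_by_label[l] == "variance" for l, _ in entries])

    def pack(x):
        z = x.copy()
        z[is_var] = np.log(np.maximum(x[is_var], 1e-12))
        return z

    def unpack(z):
        x = z.copy()
        x[is_var] = np.exp(np.clip(z[is_var], -50, 50))
        return x

    scale = 1.0 / max(n_total, 1)
    res = optimize.minimize(lambda z: scale * objective(unpack(z)), pack(x0),
                            method="BFGS",
                            options={"gtol": _GRAD_TOL, "maxiter": _MAX_ITER})
    x_hat = unpack(res.x) if objective(unpack(res.x)) <= objective(x0) else x0
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-4)

    def negloglik(x):
        total = 0.0
        for g in groups:
            n_g, mean_g, _, Sn_g = stats_by_group[g]
            mu, sigma = implied_moments(spec, theta_for(x, g))
            total -= _gaussian_loglik(mu, sigma, mean_g, Sn_g, n_g)
        return total

    estimates = {}
    for (l, g), i in pos.items():
        estimates[l if g is None else f"{l}|{g}"] = float(x_hat[i])
    ses = {k: np.nan for k in estimates}
    if compute_se and converged:
        # joint information: sum of per-group informations mapped through
        # the shared/free parameter selection
        maps = {}
        for g in groups:
            M = np.zeros((spec.n_free, len(entries)))
            for r, l in enumerate(spec.labels):
                M[r, pos[(l, None)] if l in shared else pos[(l, g)]] = 1.0
            maps[g] = M
        I_joint = np.zeros((len(entries), len(entries)))
        for g in groups:
            n_g = stats_by_group[g][0]
            I_g = _information_complete(spec, theta_for(x_hat, g), n_g)
            I_joint += maps[g].T @ I_g @ maps[g]
        ses = _ses_from_information(I_joint, list(estimates))
    pvalues = _wald_p(estimates, ses)

    per_group = {}
    for g in groups:
        n_g, mean_g, S_g, Sn_g = stats_by_group[g]
        theta_g = theta_for(x_hat, g)
        mu, sigma = implied_moments(spec, theta_g)
        est_g = spec.theta_dict(theta_g)
        ses_g = {
            l: ses.get(l if l in shared else f"{l}|{g}", np.nan) for l in spec.labels
        }
        per_group[str(g)] = FitResult(
            estimates=est_g,
            ses=ses_g,
            pvalues=_wald_p(est_g, ses_g),
            loglik=float(_gaussian_loglik(mu, sigma, mean_g, Sn_g, n_g)),
            chi_square=float((n_g - 1) * ml_discrepancy(spec, theta_g, mean_g, S_g)),
            df=spec.df,
            n_used=n_g,
            converged=converged,
            missing_method="complete",
            spec=spec,
            theta=theta_g,
        )
    n_moments_total = len(groups) * spec.n_moments
    return FitResult(
        estimates=estimates,
        ses=ses,
        pvalues=pvalues,
        loglik=float(-negloglik(x_hat)),
        chi_square=float(sum(s.chi_square for s in per_group.values())),
        df=int(n_moments_total - len(entries)),
        n_used=n_total,
        converged=converged,
        missing_method="complete",
        per_group=per_group,
        theta=x_hat,
        objective=negloglik,
    )
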