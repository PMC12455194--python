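"""Synthetic cohort generation for the thalamus-hippocampus analyses.

Two generators are provided.  ``generate_cross_sectional`` emulates a
large single-visit cohort: regional brain volumes drawn from a
multivariate normal with configurable moments, demographic and
lifestyle covariates, a cognitive composite produced by a calibrated
linear model, and raw DSST/TMT indicator scores derived from the
composite through a one-factor measurement model.
``generate_longitudinal`` draws baseline volume pairs and then latent
change scores from the bivariate/multivariate LCS regressions with
correlated residuals; follow-up volumes use the atrophy-positive sign
convention (follow-up = baseline - change).

``apply_missingness`` masks columns MCAR or MAR (logistic in observed
predictors) to emulate the attrition from the cross-sectional to the
longitudinal sample.  Pipeline disagreement for Bland-Altman analyses
is injected by ``paired_pipeline_volumes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import presets
from .factor import calibrate_loadings

__all__ = [
    "CrossSectionalConfig",
    "LCSGeneratorConfig",
    "AgeBlock",
    "FABlock",
    "MissingnessSpec",
    "generate_cross_sectional",
    "generate_longitudinal",
    "apply_missingness",
    "paired_pipeline_volumes",
    "bivariate_config",
    "multigroup_config",
    "multivariate_age_config",
    "theta_from_config",
]


def _check_correlation(corr: np.ndarray, names: Sequence[str]) -> None:
    corr = np.asarray(corr, dtype=float)
    k = len(names)
    if corr.shape != (k, k):
        raise ValueError(f"correlation matrix shape {corr.shape} != ({k},{k})")
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin <= 0:
        raise ValueError(
            f"correlation matrix is not positive definite (min eigenvalue {eigmin:.3g})"
        )


def _check_psd(mat: np.ndarray, name: str) -> None:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    eigmin = float(np.linalg.eigvalsh(mat).min())
    if eigmin < -1e-12:
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {eigmin:.3g})")


# ---------------------------------------------------------------------------
# cross-sectional cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSectionalConfig:
    """Moments and coefficients for the single-visit cohort generator.

    Defaults reproduce the calibration preset in :mod:`deltalcs.presets`
    (volume moments, a 15-term linear cognition model, and covariate
    distributions for an aging UK community cohort).  The residual SD of
    the composite defaults to the value that makes the linear model's
    population R-squared equal ``presets.COGNITION_ADJ_R2``.
    """

    n: int = presets.N_CROSS_SECTIONAL
    volume_means: Mapping[str, float] = field(
        default_factory=lambda: dict(presets.VOLUME_MEANS))
    volume_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(presets.VOLUME_SDS))
    volume_corr: np.ndarray | None = None
    cognition_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(presets.COGNITION_COEFS))
    cognition_intercept: float = presets.COGNITION_INTERCEPT
    cognition_resid_sd: float | None = None
    indicator_corrs: tuple[float, float, float] = presets.COMPOSITE_INDICATOR_CORRS
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if set(self.volume_means) != set(self.volume_sds):
            raise ValueError("volume_means and volume_sds must cover the same regions")
        if any(sd <= 0 for sd in self.volume_sds.values()):
            raise ValueError("all volume SDs must be > 0")
        corr = self.volume_corr if self.volume_corr is not None else presets.default_volume_corr()
        _check_correlation(np.asarray(corr, float), list(self.volume_means))
        object.__setattr__(self, "volume_corr", np.asarray(corr, float))

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.volume_means)

    def linear_predictor_variance(self) -> float:
        """Analytic variance of the cognition linear predictor given the
        generator's covariate covariance structure."""
        terms = list(self.cognition_coefs)
        b = np.array([self.cognition_coefs[t] for t in terms])
        cov = np.zeros((len(terms), len(terms)))
        vol_idx = {r: i for i, r in enumerate(self.regions)}
        sds = np.array([self.volume_sds[r] for r in self.regions])
        vol_cov = self.volume_corr * np.outer(sds, sds)
        indep_var = {
            "age_y": presets.AGE_SD**2,
            "sex_male": presets.PROP_MALE * (1 - presets.PROP_MALE),
            "education_y": presets.EDUCATION_SD**2,
            "smoking_ever": presets.SMOKING_EVER_PROP * (1 - presets.SMOKING_EVER_PROP),
            "alcohol_freq": presets.ALCOHOL_SD**2,
            "sleep_h": presets.SLEEP_SD**2,
        }
        for i, ti in enumerate(terms):
            for j, tj in enumerate(terms):
                if ti in vol_idx and tj in vol_idx:
                    cov[i, j] = vol_cov[vol_idx[ti], vol_idx[tj]]
                elif i == j:
                    cov[i, j] = indep_var.get(ti, 0.0)
        return float(b @ cov @ b)

    def resolved_resid_sd(self) -> float:
        if self.cognition_resid_sd is not None:
            if self.cognition_resid_sd < 0:
                raise ValueError("cognition_resid_sd must be >= 0")
            return float(self.cognition_resid_sd)
        var_lp = self.linear_predictor_variance()
        r2 = presets.COGNITION_ADJ_R2
        return float(np.sqrt(var_lp * (1 - r2) / r2))


_CS_SCHEMA = [
    "participant_id", "age_y", "sex_male", "education_y", "smoking_ever",
    "alcohol_freq", "sleep_h", "bmi", "diabetes",
    *presets.VOLUME_ORDER, "etiv_l", "cog_composite",
    "dsst", "tmt_a_s", "tmt_b_s", "nmt",
]


def _truncated_normal(rng, mean, sd, low, size):
    """Rejection-sampled normal truncated below at ``low``."""
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < low
    return out


def generate_cross_sectional(config: CrossSectionalConfig) -> pd.DataFrame:
    """Draw the single-visit cohort table (one row per participant)."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in _CS_SCHEMA})

    regions = config.regions
    sds = np.array([config.volume_sds[r] for r in regions])
    means = np.array([config.volume_means[r] for r in regions])
    cov = config.volume_corr * np.outer(sds, sds)
    volumes = rng.multivariate_normal(means, cov, size=n, method="cholesky")

    tbl = pd.DataFrame(volumes, columns=list(regions))
    tbl.insert(0, "participant_id", np.arange(n))
    tbl["age_y"] = _truncated_normal(rng, presets.AGE_MEAN, presets.AGE_SD,
                                     presets.AGE_MIN, n)
    tbl["sex_male"] = (rng.random(n) < presets.PROP_MALE).astype(int)
    tbl["education_y"] = np.clip(
        rng.normal(presets.EDUCATION_MEAN, presets.EDUCATION_SD, n), 10, 30)
    tbl["smoking_ever"] = (rng.random(n) < presets.SMOKING_EVER_PROP).astype(int)
    tbl["alcohol_freq"] = np.clip(
        np.rint(rng.normal(presets.ALCOHOL_MEAN, presets.ALCOHOL_SD, n)), 1, 6)
    tbl["sleep_h"] = rng.normal(presets.SLEEP_MEAN, presets.SLEEP_SD, n)
    tbl["bmi"] = rng.normal(presets.BMI_MEAN, presets.BMI_SD, n)
    tbl["diabetes"] = (rng.random(n) < presets.DIABETES_PROP).astype(int)
    tbl["etiv_l"] = tbl["total_gm_l"] + tbl["total_wm_l"] + tbl["vent_csf_l"]

    lp = np.full(n, config.cognition_intercept)
    for term, coef in config.cognition_coefs.items():
        lp = lp + coef * tbl[term].to_numpy(dtype=float)
    resid_sd = config.resolved_resid_sd()
    composite = lp + rng.normal(0.0, resid_sd, n)
    tbl["cog_composite"] = composite

    # one-factor measurement model: indicators load on the standardized
    # composite, reproducing the configured composite-indicator
    # correlations when the composite is rebuilt from them
    comp_var = config.linear_predictor_variance() + resid_sd**2
    g = (composite - composite.mean()) / np.sqrt(comp_var) if comp_var > 0 else np.zeros(n)
    lam = calibrate_loadings(config.indicator_corrs)
    z = np.empty((n, 3))
    for j in range(3):
        z[:, j] = lam[j] * g + np.sqrt(max(1 - lam[j] ** 2, 0.0)) * rng.normal(size=n)
    tbl["dsst"] = np.clip(np.rint(presets.DSST_MEAN + presets.DSST_SD * z[:, 0]), 0, None)
    tbl["tmt_a_s"] = presets.TMT_A_MEDIAN_S * np.exp(presets.TMT_A_LOG_SD * z[:, 1])
    tbl["tmt_b_s"] = presets.TMT_B_MEDIAN_S * np.exp(presets.TMT_B_LOG_SD * z[:, 2])

    nmt_signal = np.zeros(n)
    for term, coef in presets.NMT_COEFS.items():
        nmt_signal += coef * (tbl[term].to_numpy() - config.volume_means[term])
    sig_var = nmt_signal.var() if n > 1 else 0.0
    noise_var = max(sig_var * (1 - presets.NMT_R2) / presets.NMT_R2, 1.0) \
        if sig_var > 0 else 1.8
    nmt = presets.NMT_MEAN + nmt_signal + rng.normal(0, np.sqrt(noise_var), n)
    tbl["nmt"] = np.clip(np.rint(nmt), 2, 12)

    return tbl[_CS_SCHEMA]


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeBlock:
    """Baseline-age block of the multivariate LCS generator (years)."""

    mean: float = presets.AGE_MEAN
    sd: float = presets.AGE_SD
    min_age: float = presets.AGE_MIN
    cov_thal_age: float = presets.PHI_T_AGE
    cov_hipp_age: float = presets.PHI_H_AGE
    gamma_age_dh: float = presets.GAMMA_AGE_DH
    gamma_age_dt: float = presets.GAMMA_AGE_DT
    interval_mean: float = presets.INTERVAL_MEAN_Y
    interval_iqr: float = presets.INTERVAL_IQR_Y
    interval_min: float = presets.INTERVAL_MIN_Y


@dataclass(frozen=True)
class FABlock:
    """Fornix mean-FA block: higher baseline FA slows both atrophies so
    follow-up volumes rise with FA at the configured slopes."""

    mean: float = presets.FORNIX_FA_MEAN
    sd: float = presets.FORNIX_FA_SD
    slope_thal: float = presets.FA_SLOPE_THAL
    slope_hipp: float = presets.FA_SLOPE_HIPP


@dataclass(frozen=True)
class LCSGeneratorConfig:
    """Parameters of the latent-change-score data-generating process.

    ``cross_coupling`` is ``(gamma_t_dh, gamma_h_dt)``: baseline
    thalamus -> hippocampal change and baseline hippocampus -> thalamic
    change.  All change scores are atrophy-positive.  ``group_overrides``
    maps a group label to replacement field values (e.g. sex-specific
    couplings) plus a ``proportion`` entry.
    """

    baseline_means: tuple[float, float] = presets.BASELINE_MEANS
    baseline_cov: tuple = presets.BASELINE_COV
    self_feedback: tuple[float, float] = (presets.BETA_T, presets.BETA_H)
    cross_coupling: tuple[float, float] = (presets.GAMMA_T_DH, presets.GAMMA_H_DT)
    change_intercepts: tuple[float, float] | None = None
    change_means: tuple[float, float] = presets.CHANGE_MEANS
    change_resid_cov: tuple = ((presets.PSI_T, presets.RHO_HT),
                               (presets.RHO_HT, presets.PSI_H))
    group_overrides: Mapping[str, Mapping] | None = None
    age_block: AgeBlock | None = None
    fa_block: FABlock | None = None
    seed: int = 0

    def __post_init__(self):
        _check_psd(np.asarray(self.baseline_cov, float), "baseline_cov")
        _check_psd(np.asarray(self.change_resid_cov, float), "change_resid_cov")
        if self.group_overrides is not None:
            for g, over in self.group_overrides.items():
                bad = set(over) - {
                    "baseline_means", "baseline_cov", "self_feedback",
                    "cross_coupling", "change_intercepts", "change_means",
                    "change_resid_cov", "proportion",
                }
                if bad:
                    raise ValueError(f"unknown override fields for group {g!r}: {sorted(bad)}")

    def resolved_intercepts(self) -> tuple[float, float]:
        """Intercepts (alpha_t, alpha_h): either given explicitly or
        calibrated so the population change means equal ``change_means``."""
        if self.change_intercepts is not None:
            return tuple(float(a) for a in self.change_intercepts)
        bt, bh = self.self_feedback
        g_tdh, g_hdt = self.cross_coupling
        mu_t, mu_h = self.baseline_means
        m_dt, m_dh = self.change_means
        alpha_t = m_dt - (bt * mu_t + g_hdt * mu_h)
        alpha_h = m_dh - (g_tdh * mu_t + bh * mu_h)
        if self.age_block is not None:
            alpha_t -= self.age_block.gamma_age_dt * self.age_block.mean
            alpha_h -= self.age_block.gamma_age_dh * self.age_block.mean
        return float(alpha_t), float(alpha_h)

    def for_group(self, label: str) -> "LCSGeneratorConfig":
        if not self.group_overrides or label not in self.group_overrides:
            raise ValueError(f"group label {label!r} requested without overrides")
        over = {k: v for k, v in self.group_overrides[label].items() if k != "proportion"}
        return replace(self, group_overrides=None, **over)


_LONG_SCHEMA = [
    "participant_id", "group", "thal_t1_ml", "hipp_t1_ml",
    "thal_t2_ml", "hipp_t2_ml", "d_thal_ml", "d_hipp_ml",
    "age_y", "interval_y", "fornix_fa",
]


def _generate_longitudinal_block(config: LCSGeneratorConfig, n: int,
                                 rng: np.random.Generator) -> pd.DataFrame:
    mu = np.asarray(config.baseline_means, float)
    phi = np.asarray(config.baseline_cov, float)
    bt, bh = config.self_feedback
    g_tdh, g_hdt = config.cross_coupling
    alpha = np.array(config.resolved_intercepts())
    psi = np.asarray(config.change_resid_cov, float)
    # rows: (d_thal, d_hipp) on columns (thal_t1, hipp_t1)
    B = np.array([[bt, g_hdt], [g_tdh, bh]])

    tbl = pd.DataFrame(index=range(n), columns=_LONG_SCHEMA, dtype=float)
    tbl["group"] = ""
    if config.age_block is not None:
        ab = config.age_block
        exo_mu = np.array([mu[0], mu[1], ab.mean])
        exo_cov = np.array([
            [phi[0, 0], phi[0, 1], ab.cov_thal_age],
            [phi[0, 1], phi[1, 1], ab.cov_hipp_age],
            [ab.cov_thal_age, ab.cov_hipp_age, ab.sd**2],
        ])
        _check_psd(exo_cov, "baseline+age covariance")
        draws = rng.multivariate_normal(exo_mu, exo_cov, size=n, method="cholesky")
        young = draws[:, 2] < ab.min_age
        while young.any():
            draws[young] = rng.multivariate_normal(
                exo_mu, exo_cov, size=int(young.sum()), method="cholesky")
            young = draws[:, 2] < ab.min_age
        x = draws[:, :2]
        age = draws[:, 2]
        # IQR = 1.349 sd for a normal; clipped below at interval_min
        interval = np.maximum(
            rng.normal(ab.interval_mean, ab.interval_iqr / 1.349, n), ab.interval_min)
        tbl["age_y"] = age
        tbl["interval_y"] = interval
        age_effect = np.column_stack([ab.gamma_age_dt * age, ab.gamma_age_dh * age])
    else:
        x = rng.multivariate_normal(mu, phi, size=n, method="cholesky")
        age_effect = 0.0

    if psi.any():
        eps = rng.multivariate_normal(np.zeros(2), psi, size=n, method="cholesky")
    else:
        eps = np.zeros((n, 2))
    d = alpha + x @ B.T + age_effect + eps  # columns (d_thal, d_hipp)

    if config.fa_block is not None:
        fb = config.fa_block
        fa = rng.normal(fb.mean, fb.sd, n)
        d[:, 0] -= fb.slope_thal * (fa - fb.mean)
        d[:, 1] -= fb.slope_hipp * (fa - fb.mean)
        tbl["fornix_fa"] = fa

    tbl["thal_t1_ml"] = x[:, 0]
    tbl["hipp_t1_ml"] = x[:, 1]
    tbl["d_thal_ml"] = d[:, 0]
    tbl["d_hipp_ml"] = d[:, 1]
    # atrophy-positive convention: follow-up = baseline - change
    tbl["thal_t2_ml"] = x[:, 0] - d[:, 0]
    tbl["hipp_t2_ml"] = x[:, 1] - d[:, 1]
    return tbl


def generate_longitudinal(config: LCSGeneratorConfig, n: int) -> pd.DataFrame:
    """Draw a two-timepoint cohort of ``n`` participants.

    With ``group_overrides`` the cohort is partitioned by the configured
    group proportions and each block generated at its own parameters.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(config.seed)
    if n == 0:
        out = pd.DataFrame({c: pd.Series(dtype=float) for c in _LONG_SCHEMA})
        out["group"] = out["group"].astype(str)
        return out

    if config.group_overrides:
        labels = list(config.group_overrides)
        props = np.array([
            config.group_overrides[g].get("proportion", 1.0 / len(labels))
            for g in labels
        ], dtype=float)
        props = props / props.sum()
        counts = np.floor(props * n).astype(int)
        for i in np.argsort(-(props * n - counts))[: n - counts.sum()]:
            counts[i] += 1
        blocks = []
        for g, n_g in zip(labels, counts):
            block = _generate_longitudinal_block(config.for_group(g), int(n_g), rng)
            block["group"] = str(g)
            blocks.append(block)
        tbl = pd.concat(blocks, ignore_index=True)
    else:
        tbl = _generate_longitudinal_block(config, n, rng)
    tbl["participant_id"] = np.arange(len(tbl), dtype=float)
    return tbl[_LONG_SCHEMA]


# ---------------------------------------------------------------------------
# preset configurations
# ---------------------------------------------------------------------------

def bivariate_config(seed: int = 0, **overrides) -> LCSGeneratorConfig:
    """Bivariate LCS generator at the calibrated study parameters."""
    return LCSGeneratorConfig(seed=seed, **overrides)


def multigroup_config(seed: int = 0) -> LCSGeneratorConfig:
    """Sex-stratified generator: group-specific cross-couplings with the
    cohort's female/male split."""
    return LCSGeneratorConfig(
        seed=seed,
        group_overrides={
            "female": {"cross_coupling": presets.GAMMA_FEMALE,
                       "proportion": 1 - presets.PROP_MALE},
            "male": {"cross_coupling": presets.GAMMA_MALE,
                     "proportion": presets.PROP_MALE},
        },
    )


def multivariate_age_config(seed: int = 0) -> LCSGeneratorConfig:
    """Age-augmented generator: baseline age covaries negatively with both
    baselines and accelerates hippocampal atrophy."""
    return LCSGeneratorConfig(
        seed=seed,
        cross_coupling=(presets.GAMMA_T_DH_AGE, presets.GAMMA_H_DT_AGE),
        age_block=AgeBlock(),
    )


def theta_from_config(config: LCSGeneratorConfig) -> dict[str, float]:
    """Generating parameter values keyed by the engine's labels, for the
    spec produced by ``bivariate_lcs_spec``/``multivariate_age_spec``."""
    phi = np.asarray(config.baseline_cov, float)
    psi = np.asarray(config.change_resid_cov, float)
    alpha_t, alpha_h = config.resolved_intercepts()
    theta = {
        "mu_thal": config.baseline_means[0],
        "mu_hipp": config.baseline_means[1],
        "var_thal": phi[0, 0],
        "var_hipp": phi[1, 1],
        "phi_ht": phi[0, 1],
        "alpha_thal": alpha_t,
        "alpha_hipp": alpha_h,
        "beta_t": config.self_feedback[0],
        "beta_h": config.self_feedback[1],
        "gamma_t_dh": config.cross_coupling[0],
        "gamma_h_dt": config.cross_coupling[1],
        "psi_thal": psi[0, 0],
        "psi_hipp": psi[1, 1],
        "rho_ht": psi[0, 1],
    }
    if config.age_block is not None:
        ab = config.age_block
        theta.update({
            "mu_age": ab.mean,  # pre-truncation location
            "var_age": ab.sd**2,
            "phi_t_age": ab.cov_thal_age,
            "phi_h_age": ab.cov_hipp_age,
            "gamma_age_dh": ab.gamma_age_dh,
            "gamma_age_dt": ab.gamma_age_dt,
        })
    return theta


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissingnessSpec:
    """Row-level masking of target columns, MCAR or MAR (logistic)."""

    mechanism: str = "MCAR"
    target_columns: tuple[str, ...] = ("thal_t2_ml", "hipp_t2_ml")
    rate: float = 0.85
    mar_predictors: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError("mechanism must be MCAR or MAR")
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must be in [0, 1]")
        if self.mechanism == "MAR" and not self.mar_predictors:
            raise ValueError("MAR requires mar_predictors with logistic weights")


def apply_missingness(table: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Return a masked copy; all target columns are blanked together per
    selected row (the original table is untouched).  The realized
    missingness rate is recorded in ``result.attrs``."""
    unknown = [c for c in spec.target_columns if c not in table.columns]
    if unknown:
        raise ValueError(f"unknown target columns {unknown}")
    out = table.copy()
    n = len(out)
    rng = np.random.default_rng(spec.seed)
    if n == 0:
        out.attrs["realized_missing_rate"] = 0.0
        return out
    if spec.mechanism == "MCAR":
        mask = rng.random(n) < spec.rate
    else:
        unknown = [c for c in spec.mar_predictors if c not in table.columns]
        if unknown:
            raise ValueError(f"unknown MAR predictor columns {unknown}")
        eta = np.zeros(n)
        for col, w in spec.mar_predictors.items():
            x = table[col].to_numpy(dtype=float)
            eta += w * (x - np.nanmean(x))
        if spec.rate in (0.0, 1.0):
            mask = np.full(n, bool(spec.rate))
        else:
            # calibrate the intercept so the expected rate matches
            c = optimize.brentq(
                lambda c0: np.mean(1 / (1 + np.exp(-(c0 + eta)))) - spec.rate,
                -50, 50)
            mask = rng.random(n) < 1 / (1 + np.exp(-(c + eta)))
    out.loc[mask, list(spec.target_columns)] = np.nan
    out.attrs["realized_missing_rate"] = float(mask.mean())
    return out


# ---------------------------------------------------------------------------
# paired segmentation-pipeline disagreement
# ---------------------------------------------------------------------------

def paired_pipeline_volumes(
    volumes: np.ndarray | pd.Series,
    bias: float = presets.PIPELINE_BIAS_ML,
    noise_sd: float = presets.PIPELINE_NOISE_SD_ML,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a second segmentation pipeline's estimates of the same
    structures: pipeline2 = pipeline1 + bias + noise (mL)."""
    v1 = np.asarray(volumes, dtype=float)
    rng = np.random.default_rng(seed)
    v2 = v1 + bias + rng.normal(0.0, noise_sd, v1.shape)
    return pd.DataFrame({"pipeline1_ml": v1, "pipeline2_ml": v2})
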