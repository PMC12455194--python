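"""Calibration presets for the synthetic aging-cohort generator.

The preset numbers describe a UK-Biobank-style cohort of cognitively
unimpaired adults over 60: regional brain volumes in mL (whole-brain
totals in L), demographic and lifestyle covariates, a cognitive
composite built from digit-symbol substitution (DSST) and trail-making
(TMT-A/B) scores, and the longitudinal thalamus-hippocampus latent
change score (LCS) parameters used throughout the package.

All change scores follow the atrophy-positive convention: a positive
change means volume loss between the baseline and follow-up scan
(follow-up = baseline - change).
"""

from __future__ import annotations

import numpy as np

# --- cross-sectional cohort size and longitudinal follow-up ---------------
N_CROSS_SECTIONAL = 4348
N_LONGITUDINAL = 653
PROP_MALE = 0.454

# --- regional volume moments (mL unless noted) ----------------------------
VOLUME_MEANS = {
    "thalamus_ml": 14.95,
    "hippocampus_ml": 7.52,
    "amygdala_ml": 2.46,
    "caudate_ml": 6.85,
    "putamen_ml": 9.36,
    "pallidum_ml": 3.49,
    "accumbens_ml": 0.83,
    "frontal_gm_ml": 48.9,
    "total_wm_l": 0.54,   # litres
    "total_gm_l": 0.60,   # litres; GM+WM total 1.14 L
    "vent_csf_l": 0.03,   # litres; eTIV = GM+WM+ventricular CSF = 1.17 L
}

VOLUME_SDS = {
    "thalamus_ml": 1.34,
    "hippocampus_ml": 0.85,
    "amygdala_ml": 0.43,
    "caudate_ml": 0.81,
    "putamen_ml": 1.07,
    "pallidum_ml": 0.46,
    "accumbens_ml": 0.20,
    "frontal_gm_ml": 5.83,
    "total_wm_l": 0.06,
    "total_gm_l": 0.08,
    "vent_csf_l": 0.01,
}

VOLUME_ORDER = tuple(VOLUME_MEANS)

# baseline thalamus-hippocampus covariance 0.76 mL^2 -> correlation 0.667
THAL_HIPP_CORR = 0.76 / (1.34 * 0.85)


def default_volume_corr() -> np.ndarray:
    """Structural-covariance correlation matrix for the volume block.

    Regional GM structures correlate moderately with one another and
    with the global GM/WM totals; ventricular CSF is nearly independent
    of tissue volumes.  The thalamus-hippocampus entry is pinned to the
    value implied by their covariance of 0.76 mL^2.
    """
    k = len(VOLUME_ORDER)
    idx = {name: i for i, name in enumerate(VOLUME_ORDER)}
    corr = np.full((k, k), 0.45)
    gm = idx["total_gm_l"]
    wm = idx["total_wm_l"]
    csf = idx["vent_csf_l"]
    corr[gm, :] = corr[:, gm] = 0.55
    corr[wm, :] = corr[:, wm] = 0.35
    corr[gm, wm] = corr[wm, gm] = 0.45
    corr[csf, :] = corr[:, csf] = 0.05
    t, h = idx["thalamus_ml"], idx["hippocampus_ml"]
    corr[t, h] = corr[h, t] = THAL_HIPP_CORR
    np.fill_diagonal(corr, 1.0)
    return corr


# --- demographics / lifestyle ---------------------------------------------
AGE_MEAN, AGE_SD, AGE_MIN = 67.9, 4.8, 60.0
EDUCATION_MEAN, EDUCATION_SD = 17.2, 2.3
SMOKING_EVER_PROP = 0.463          # past + current smokers
ALCOHOL_MEAN, ALCOHOL_SD = 2.73, 1.42   # 1 (daily) .. 6 (never)
SLEEP_MEAN, SLEEP_SD = 7.2, 1.0
# propensity-model stand-ins, not calibrated to any published table
BMI_MEAN, BMI_SD = 27.0, 4.5
DIABETES_PROP = 0.07

# --- cross-sectional cognition model (composite-score units) --------------
# multivariable linear model of the cognitive composite; WM total in L
COGNITION_INTERCEPT = 0.817
COGNITION_COEFS = {
    "thalamus_ml": 0.069,
    "frontal_gm_ml": 0.008,
    "age_y": -0.039,
    "sex_male": -0.053,
    "education_y": 0.030,
    "smoking_ever": 0.020,
    "alcohol_freq": -0.034,
    "sleep_h": -0.007,
    "total_wm_l": -0.004,
    "hippocampus_ml": 0.024,
    "caudate_ml": -0.015,
    "putamen_ml": 0.035,
    "pallidum_ml": 0.004,
    "amygdala_ml": -0.069,
    "accumbens_ml": -0.001,
}
COGNITION_ADJ_R2 = 0.09

# composite-indicator correlations the one-factor measurement model is
# calibrated to reproduce (DSST, TMT-A time, TMT-B time)
COMPOSITE_INDICATOR_CORRS = (0.66, -0.78, -0.93)
INDICATOR_COLUMNS = ("dsst", "tmt_a_s", "tmt_b_s")

# raw indicator scales: DSST correct matches; TMT times in seconds,
# log-normal with modest dispersion so the linear factor structure holds
DSST_MEAN, DSST_SD = 19.0, 5.0
TMT_A_MEDIAN_S, TMT_A_LOG_SD = 40.0, 0.12
TMT_B_MEDIAN_S, TMT_B_LOG_SD = 80.0, 0.15

# numeric memory test (max digits, 2..12); weak volumetric signal
NMT_COEFS = {"thalamus_ml": 0.10, "frontal_gm_ml": 0.03, "hippocampus_ml": 0.04}
NMT_MEAN, NMT_R2 = 6.7, 0.027

# --- longitudinal LCS parameters (atrophy-positive, mL) -------------------
BASELINE_MEANS = (14.95, 7.52)                  # (thalamus, hippocampus)
BASELINE_COV = ((1.34**2, 0.76), (0.76, 0.85**2))

GAMMA_T_DH = -0.048    # baseline thalamus -> hippocampal atrophy
GAMMA_H_DT = 0.043     # baseline hippocampus -> thalamic atrophy
BETA_T = 0.02          # self-feedback, thalamus
BETA_H = 0.02          # self-feedback, hippocampus
PHI_HT = 0.76          # baseline covariance (mL^2)
RHO_HT = 0.03          # change-score residual covariance (mL^2)
# residual variances: smallest round value keeping the residual
# correlation (rho/psi ~ 0.91) inside the unit disc with margin; the
# implied change-score SD is ~0.19 mL over the ~2.3 y interval
PSI_T = 0.033
PSI_H = 0.033

CHANGE_MEANS = (0.213, 0.155)                   # (dThal, dHipp) mL

# sex-stratified couplings (gamma_t_dh, gamma_h_dt)
GAMMA_FEMALE = (-0.057, 0.049)
GAMMA_MALE = (-0.040, 0.008)

# age-augmented model
PHI_T_AGE = -1.63      # cov(baseline thalamus, age) mL*y
PHI_H_AGE = -1.10      # cov(baseline hippocampus, age) mL*y
GAMMA_AGE_DH = 0.013   # baseline age -> hippocampal atrophy (mL/y)
GAMMA_AGE_DT = 0.0     # age -> thalamic atrophy: no association
GAMMA_T_DH_AGE = -0.042
GAMMA_H_DT_AGE = 0.048

INTERVAL_MEAN_Y, INTERVAL_IQR_Y, INTERVAL_MIN_Y = 2.26, 0.33, 1.5

# fornix structural-connectivity block: mean FA and slopes of follow-up
# volume on baseline FA (mL per FA unit)
FORNIX_FA_MEAN, FORNIX_FA_SD = 0.45, 0.05
FA_SLOPE_THAL = 0.48
FA_SLOPE_HIPP = 0.62

# segmentation-pipeline disagreement (pipeline2 - pipeline1), mL
PIPELINE_BIAS_ML = 0.12
PIPELINE_NOISE_SD_ML = 0.25
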