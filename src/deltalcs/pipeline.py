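"""End-to-end orchestration of the cross-sectional (Aim-1) and
longitudinal (Aim-2) analyses over synthetic or user-supplied tables.

Aim-1: build the cognitive composite from the DSST/TMT indicators,
fit the multivariable linear model of the composite on thalamus volume
plus demographic/lifestyle/volumetric covariates, the numeric-memory
model, the eTIV sensitivity variant, VIF screening and FDR-adjusted
thalamus p-values.

Aim-2: session test for longitudinal volume loss, the bivariate LCS
fit, optional sex-stratified multigroup and age-augmented fits, and the
selection-bias sensitivity suite (propensity-matched refit, FIML,
PMM multiple imputation with Rubin pooling) plus the segmentation
agreement analysis.

All stage seeds derive from the run seed, so a rerun with the same
configuration is reproducible end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .agreement import bland_altman
from .factor import add_composite
from .lcs import (bivariate_lcs_spec, fit_fiml, fit_ml, fit_multigroup,
                  multivariate_age_spec)
from .missing import (attrition_table, estimate_propensity, impute_pmm,
                      match_nearest, pool_rubin)
from .regression import bh_fdr, fit_ols, fit_session_lmm, to_long_sessions, vif
from .synthetic import (CrossSectionalConfig, MissingnessSpec, apply_missingness,
                        generate_cross_sectional, multigroup_config,
                        multivariate_age_config, paired_pipeline_volumes,
                        generate_longitudinal)

__all__ = ["RunConfig", "run_aim1", "run_aim2", "write_report"]

AIM1_TERMS = list(presets.COGNITION_COEFS)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (typically read from YAML)."""

    seed: int = 0
    out_dir: str | Path = "deltalcs_out"
    input_csv: str | None = None      # optional pre-generated cohort table
    n_cross_sectional: int = presets.N_CROSS_SECTIONAL
    n_longitudinal: int = presets.N_LONGITUDINAL
    analyses: dict = field(default_factory=lambda: {
        "aim1": True, "aim2": True, "multigroup": True,
        "multivariate_age": True, "fiml": True, "mi": True, "psm": True,
        "agreement": True, "connectivity": False,
    })
    mi_m: int = 40
    mi_k_donors: int = 5
    psm_caliper: float = 0.001
    agreement_pairs: int = 125

    def __post_init__(self):
        if not any(self.analyses.values()):
            raise ValueError("at least one analysis must be enabled")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items() if k != "analyses"})
        if "analyses" in d:
            cfg.analyses.update(d["analyses"])
            if not any(cfg.analyses.values()):
                raise ValueError("at least one analysis must be enabled")
        return cfg


def _require(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"required column(s) missing: {missing}")


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Aim 1
# ---------------------------------------------------------------------------

def run_aim1(config: RunConfig) -> dict:
    """Cross-sectional thalamus-cognition analysis; returns the report
    dict and writes CSV/JSON artifacts to the output directory."""
    if not config.analyses.get("aim1", False):
        raise ValueError("aim1 analysis is disabled in this configuration")
    out = _outdir(config)
    if config.input_csv:
        table = pd.read_csv(config.input_csv)
    else:
        table = generate_cross_sectional(
            CrossSectionalConfig(n=config.n_cross_sectional, seed=config.seed))
    _require(table, AIM1_TERMS + ["dsst", "tmt_a_s", "tmt_b_s", "nmt"])

    table, solution = add_composite(table)
    rhs = " + ".join(AIM1_TERMS)
    main = fit_ols(table, f"cog_composite ~ {rhs}")
    nmt = fit_ols(table, f"nmt ~ {rhs}")
    etiv = fit_ols(table, f"cog_composite ~ {rhs} + etiv_l") \
        if "etiv_l" in table.columns else None

    vif_main = vif(table, AIM1_TERMS)
    vif_etiv = vif(table, AIM1_TERMS + ["etiv_l"]) if etiv is not None else None

    # thalamus association across composite + raw-score models, BH-adjusted
    raw_models = {"cog_composite": main, "nmt": nmt}
    for score in ("dsst", "tmt_a_s", "tmt_b_s"):
        raw_models[score] = fit_ols(table, f"{score} ~ {rhs}")
    fdr_rows = pd.DataFrame({
        "outcome": list(raw_models),
        "thalamus_beta": [m.coefficients["thalamus_ml"] for m in raw_models.values()],
        "p": [m.pvalues["thalamus_ml"] for m in raw_models.values()],
    })
    fdr_rows["p_fdr"] = bh_fdr(fdr_rows["p"].to_numpy())

    _write_csv(main.to_frame(), out / "aim1_main_model.csv")
    _write_csv(nmt.to_frame(), out / "aim1_nmt_model.csv")
    if etiv is not None:
        _write_csv(etiv.to_frame(), out / "aim1_etiv_model.csv")
        _write_csv(vif_etiv, out / "aim1_vif_etiv.csv")
    _write_csv(vif_main, out / "aim1_vif.csv")
    _write_csv(fdr_rows, out / "aim1_fdr.csv")

    report = {
        "n": int(main.n),
        "factor_solution": json.loads(solution.to_json()),
        "main_model": {
            "thalamus_beta": main.coefficients["thalamus_ml"],
            "thalamus_se": main.ses["thalamus_ml"],
            "thalamus_p": main.pvalues["thalamus_ml"],
            "adj_r_squared": main.adj_r_squared,
            "n_predictors": len(main.terms) - 1,
        },
        "nmt_model": {
            "thalamus_beta": nmt.coefficients["thalamus_ml"],
            "thalamus_p": nmt.pvalues["thalamus_ml"],
            "r_squared": nmt.r_squared,
        },
        "etiv_sensitivity": None if etiv is None else {
            "thalamus_beta": etiv.coefficients["thalamus_ml"],
            "thalamus_p": etiv.pvalues["thalamus_ml"],
            "etiv_vif": float(vif_etiv.loc[vif_etiv.term == "etiv_l", "vif"].iloc[0]),
        },
        "max_vif": float(vif_main["vif"].max()),
        "fdr": fdr_rows.to_dict("records"),
        "seed": config.seed,
    }
    (out / "aim1_summary.json").write_text(json.dumps(report, indent=2, default=float))
    return report


# ---------------------------------------------------------------------------
# Aim 2
# ---------------------------------------------------------------------------

def _lcs_frame(fit) -> pd.DataFrame:
    return fit.to_frame()


def run_aim2(config: RunConfig) -> dict:
    """Longitudinal thalamus-hippocampus LCS analysis with sensitivity
    suite; returns the report dict and writes artifacts."""
    if not config.analyses.get("aim2", False):
        raise ValueError("aim2 analysis is disabled in this configuration")
    out = _outdir(config)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    if config.input_csv:
        full = pd.read_csv(config.input_csv)
        _require(full, ["thal_t1_ml", "thal_t2_ml", "hipp_t1_ml", "hipp_t2_ml"])
        if full[["thal_t2_ml", "hipp_t2_ml"]].dropna().empty:
            raise ValueError("no rows with follow-up volumes: need 2 timepoints")
        masked = full
    else:
        gen_cfg = multivariate_age_config(seed=int(seeds[0]))
        full = generate_longitudinal(gen_cfg, config.n_cross_sectional)
        # lifestyle stand-ins drive the attrition model
        aux = np.random.default_rng(int(seeds[1]))
        full["smoking_ever"] = (aux.random(len(full)) < presets.SMOKING_EVER_PROP).astype(int)
        full["alcohol_freq"] = np.clip(
            np.rint(aux.normal(presets.ALCOHOL_MEAN, presets.ALCOHOL_SD, len(full))), 1, 6)
        full["bmi"] = aux.normal(presets.BMI_MEAN, presets.BMI_SD, len(full))
        full["diabetes"] = (aux.random(len(full)) < presets.DIABETES_PROP).astype(int)
        rate = 1.0 - config.n_longitudinal / config.n_cross_sectional
        masked = apply_missingness(full, MissingnessSpec(
            mechanism="MAR", target_columns=("thal_t2_ml", "hipp_t2_ml"),
            rate=rate, mar_predictors={"bmi": 0.05, "smoking_ever": 0.3},
            seed=int(seeds[2])))

    has_fu = masked[["thal_t2_ml", "hipp_t2_ml"]].notna().all(axis=1)
    aim2 = masked[has_fu].copy()
    report: dict = {"n_full": int(len(masked)), "n_longitudinal": int(len(aim2)),
                    "seed": config.seed}

    # session tests
    session = {}
    for region, (b, f) in {"thalamus": ("thal_t1_ml", "thal_t2_ml"),
                           "hippocampus": ("hipp_t1_ml", "hipp_t2_ml")}.items():
        st = fit_session_lmm(to_long_sessions(aim2, b, f))
        session[region] = {"session_effect": st.session_effect,
                           "t": st.session_t, "p": st.session_p}
    report["session_tests"] = session

    # core bivariate LCS
    spec = bivariate_lcs_spec()
    fit = fit_ml(spec, aim2)
    if not fit.converged:
        raise RuntimeError("bivariate LCS did not converge")
    _write_csv(_lcs_frame(fit), out / "aim2_bivariate_lcs.csv")
    report["bivariate_lcs"] = {k: {"estimate": fit.estimates[k],
                                   "se": fit.ses[k], "p": fit.pvalues[k]}
                               for k in ("gamma_t_dh", "gamma_h_dt",
                                         "phi_ht", "rho_ht", "beta_t", "beta_h")}

    if config.analyses.get("multigroup", False):
        mg_table = generate_longitudinal(multigroup_config(seed=int(seeds[3])),
                                         config.n_longitudinal)
        mg = fit_multigroup(spec, mg_table, "group")
        _write_csv(mg.to_frame(), out / "aim2_multigroup_lcs.csv")
        report["multigroup_lcs"] = {
            g: {"gamma_t_dh": sub.estimates["gamma_t_dh"],
                "gamma_h_dt": sub.estimates["gamma_h_dt"]}
            for g, sub in mg.per_group.items()}

    if config.analyses.get("multivariate_age", False) and "age_y" in aim2.columns:
        age_fit = fit_ml(multivariate_age_spec(), aim2)
        _write_csv(_lcs_frame(age_fit), out / "aim2_multivariate_age_lcs.csv")
        report["multivariate_age_lcs"] = {
            k: {"estimate": age_fit.estimates[k], "se": age_fit.ses[k],
                "p": age_fit.pvalues[k]}
            for k in ("gamma_t_dh", "gamma_h_dt", "gamma_age_dh", "gamma_age_dt")}

    # sensitivity suite -----------------------------------------------------
    psm_cols = [c for c in ("smoking_ever", "alcohol_freq", "diabetes", "bmi")
                if c in masked.columns]
    if config.analyses.get("psm", False) and psm_cols:
        membership = has_fu.astype(int)
        scores = estimate_propensity(
            masked.assign(_member=membership), psm_cols, "_member")
        match = match_nearest(scores, membership, caliper=config.psm_caliper,
                              seed=int(seeds[4]))
        matched_ids = [a for a, _ in match.pairs]
        psm_fit = fit_ml(spec, masked.loc[matched_ids])
        _write_csv(_lcs_frame(psm_fit), out / "aim2_psm_lcs.csv")
        report["psm"] = {
            "match_rate": match.match_rate, "n_matched": len(match.pairs),
            "gamma_t_dh": psm_fit.estimates["gamma_t_dh"],
            "gamma_t_dh_se": psm_fit.ses["gamma_t_dh"]}
        _write_csv(attrition_table(masked, has_fu, psm_cols),
                   out / "aim2_attrition.csv")

    if config.analyses.get("fiml", False):
        fiml_fit = fit_fiml(spec, masked)
        _write_csv(_lcs_frame(fiml_fit), out / "aim2_fiml_lcs.csv")
        report["fiml"] = {"gamma_t_dh": fiml_fit.estimates["gamma_t_dh"],
                          "gamma_t_dh_se": fiml_fit.ses["gamma_t_dh"],
                          "n_used": fiml_fit.n_used}

    if config.analyses.get("mi", False):
        predictors = [c for c in ("thal_t1_ml", "hipp_t1_ml", "age_y")
                      if c in masked.columns]
        imp = impute_pmm(masked, ("thal_t2_ml", "hipp_t2_ml"), predictors,
                         m=config.mi_m, k_donors=config.mi_k_donors,
                         seed=int(seeds[5]))
        per_label: dict[str, list] = {}
        per_var: dict[str, list] = {}
        for t in imp.tables:
            f = fit_ml(spec, t)
            for k in f.estimates:
                per_label.setdefault(k, []).append(f.estimates[k])
                per_var.setdefault(k, []).append(f.ses[k] ** 2)
        dfcom = len(masked) - spec.n_free
        pooled_rows = []
        for k in per_label:
            pe = pool_rubin(per_label[k], per_var[k], dfcom=dfcom)
            pooled_rows.append({"label": k, "estimate": pe.estimate, "se": pe.se,
                                "df": pe.df, "p": pe.p})
        pooled = pd.DataFrame(pooled_rows)
        _write_csv(pooled, out / "aim2_mi_pooled.csv")
        g = pooled.set_index("label").loc["gamma_t_dh"]
        report["mi"] = {"m": imp.m, "gamma_t_dh": float(g["estimate"]),
                        "gamma_t_dh_se": float(g["se"]), "df": float(g["df"])}

    if config.analyses.get("agreement", False):
        n_pairs = min(config.agreement_pairs, len(aim2))
        sel = aim2.sample(n=n_pairs, random_state=int(seeds[6]) % 2**32)
        agr = {}
        for label, col in {"thalamus_baseline": "thal_t1_ml",
                           "thalamus_followup": "thal_t2_ml",
                           "hippocampus_baseline": "hipp_t1_ml",
                           "hippocampus_followup": "hipp_t2_ml"}.items():
            paired = paired_pipeline_volumes(sel[col], seed=int(seeds[7]))
            summary, plot_data = bland_altman(paired["pipeline1_ml"],
                                              paired["pipeline2_ml"])
            _write_csv(plot_data, out / f"aim2_bland_altman_{label}.csv")
            agr[label] = json.loads(summary.to_json())
        report["agreement"] = agr

    if config.analyses.get("connectivity", False) and "fornix_fa" in aim2.columns \
            and aim2["fornix_fa"].notna().any():
        conn = {}
        for region, (fu, base) in {"thalamus": ("thal_t2_ml", "thal_t1_ml"),
                                   "hippocampus": ("hipp_t2_ml", "hipp_t1_ml")}.items():
            covs = [c for c in ("age_y", "interval_y") if c in aim2.columns]
            f = fit_ols(aim2, f"{fu} ~ fornix_fa + {base}"
                        + ("" if not covs else " + " + " + ".join(covs)))
            conn[region] = {"fa_beta": f.coefficients["fornix_fa"],
                            "fa_p": f.pvalues["fornix_fa"]}
        report["connectivity"] = conn

    (out / "aim2_summary.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def write_report(out_dir: str | Path) -> Path:
    """Consolidate the JSON summaries in ``out_dir`` into a plain-text
    report."""
    out = Path(out_dir)
    lines = ["deltalcs consolidated report", "=" * 30]
    for name in ("aim1_summary.json", "aim2_summary.json"):
        path = out / name
        if not path.exists():
            continue
        lines.append("")
        lines.append(name.replace("_summary.json", "").upper())
        lines.append("-" * 20)
        lines.append(json.dumps(json.loads(path.read_text()), indent=2))
    target = out / "report.txt"
    target.write_text("\n".join(lines) + "\n")
    return target
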