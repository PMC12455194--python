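"""Cognitive composite: one-factor EFA over DSST and TMT scores.

With exactly three indicators the single-factor model is just
identified and has the Spearman closed form

    lambda_1 = sqrt(r12 * r13 / r23)   (and cyclically),

which coincides with the iterative ML solution.  Composite scores are
regression (Thomson) factor scores on standardized indicators, with the
orientation flipped so that a higher score means better performance
(more DSST matches, shorter TMT times).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSolution",
    "standardize",
    "efa_one_factor",
    "composite_scores",
    "add_composite",
    "calibrate_loadings",
]


@dataclass(frozen=True)
class FactorSolution:
    """One-factor solution over standardized indicators."""

    indicators: tuple[str, ...]
    loadings: tuple[float, ...]
    orientation: int = 1

    def __post_init__(self):
        if len(self.indicators) != len(self.loadings):
            raise ValueError("one loading per indicator required")
        if abs(self.orientation) != 1:
            raise ValueError("orientation must be +1 or -1")

    @property
    def uniquenesses(self) -> tuple[float, ...]:
        return tuple(1.0 - l**2 for l in self.loadings)

    @property
    def variance_explained(self) -> float:
        return float(np.mean([l**2 for l in self.loadings]))

    def oriented_loadings(self) -> np.ndarray:
        return self.orientation * np.asarray(self.loadings)

    def implied_corr(self) -> np.ndarray:
        lam = np.asarray(self.loadings)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        return R

    def to_json(self) -> str:
        return json.dumps(
            {
                "indicators": list(self.indicators),
                "loadings": list(self.loadings),
                "uniquenesses": list(self.uniquenesses),
                "variance_explained": self.variance_explained,
                "orientation": self.orientation,
            },
            indent=2,
        )


def standardize(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Copy of ``table`` with the listed columns scaled to mean 0, SD 1
    (SD with the n-1 denominator).  Zero-variance columns are rejected."""
    out = table.copy()
    for c in columns:
        x = out[c].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"column {c!r} has zero or undefined variance")
        out[c] = (x - x.mean()) / sd
    return out


def efa_one_factor(
    corr3: np.ndarray,
    indicators: Sequence[str] = ("dsst", "tmt_a_s", "tmt_b_s"),
    positive_indicator: int = 0,
) -> FactorSolution:
    """Closed-form single-factor solution for three indicators.

    The orientation is chosen so the indicator at ``positive_indicator``
    (DSST by default) loads positively: a larger composite then means
    better performance.  A negative radicand or a Heywood loading
    (|lambda| > 1) is rejected with a diagnostic.
    """
    R = np.asarray(corr3, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("corr3 must be a symmetric 3x3 matrix")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("corr3 must have a unit diagonal")
    r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
    if r23 == 0 or r12 == 0 or r13 == 0:
        raise ValueError("zero inter-indicator correlation: single factor undefined")
    rad = r12 * r13 / r23
    if rad <= 0:
        raise ValueError(
            f"negative radicand r12*r13/r23 = {rad:.4g}: correlation pattern "
            "inconsistent with a single factor"
        )
    l1 = np.sqrt(rad)
    lam = np.array([l1, r12 / l1, r13 / l1])
    if np.any(np.abs(lam) > 1 + 1e-8):
        raise ValueError(f"Heywood case: loading magnitudes {np.abs(lam)} exceed 1")
    lam = np.clip(lam, -1.0, 1.0)
    orientation = 1 if lam[positive_indicator] >= 0 else -1
    return FactorSolution(tuple(indicators), tuple(float(l) for l in lam),
                          orientation=orientation)


def composite_scores(table: pd.DataFrame, solution: FactorSolution) -> pd.Series:
    """Regression-method factor scores, positively oriented.

    Indicators are standardized against the table's own moments; the
    score weights are R^-1 lambda with R the model-implied correlation
    matrix.  Rows with any missing indicator score as missing.
    """
    cols = list(solution.indicators)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing indicator columns {missing}")
    z = standardize(table.dropna(subset=cols), cols)[cols].to_numpy(dtype=float)
    lam = np.asarray(solution.loadings)
    R = solution.implied_corr()
    w = np.linalg.solve(R, lam)
    raw = z @ w
    out = pd.Series(np.nan, index=table.index, name="cog_composite", dtype=float)
    out.loc[table.dropna(subset=cols).index] = solution.orientation * raw
    return out


def add_composite(
    table: pd.DataFrame, columns: Sequence[str] = ("dsst", "tmt_a_s", "tmt_b_s")
) -> tuple[pd.DataFrame, FactorSolution]:
    """Fit the one-factor model on ``columns`` and append the composite
    as ``cog_composite``."""
    sub = table.dropna(subset=list(columns))
    R = np.corrcoef(sub[list(columns)].to_numpy(dtype=float), rowvar=False)
    solution = efa_one_factor(R, indicators=tuple(columns))
    out = table.copy()
    out["cog_composite"] = composite_scores(table, solution)
    return out, solution


@lru_cache(maxsize=None)
def calibrate_loadings(target_corrs: tuple[float, ...]) -> tuple[float, ...]:
    """Loadings whose regression-score/indicator correlations equal the
    targets.

    For Thomson scores s = lambda' R^-1 z the score-indicator
    correlation is lambda_j / sqrt(rho) with rho = lambda' R^-1 lambda,
    so lambda = c * sqrt(rho) solves a scalar fixed point in rho.
    """
    c = np.asarray(target_corrs, dtype=float)
    if np.any(np.abs(c) >= 1):
        raise ValueError("target correlations must lie in (-1, 1)")
    t = 0.9
    for _ in range(200):
        lam = c * t
        if np.any(np.abs(lam) >= 1):
            lam = np.clip(lam, -0.999, 0.999)
        ratio = lam**2 / (1 - lam**2)
        rho = ratio.sum() / (1 + ratio.sum())
        t_new = np.sqrt(rho)
        if abs(t_new - t) < 1e-12:
            t = t_new
            break
        t = t_new
    lam = tuple(float(v) for v in c * t)
    return lam
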