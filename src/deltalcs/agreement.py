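"""Bland-Altman agreement between two measurement pipelines.

Differences are taken as (pipeline2 - pipeline1) and plotted against
the pairwise means; the limits of agreement are bias +/- 1.96 SD of the
differences, and the fraction of pairs inside the limits is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgreementSummary", "bland_altman"]

LOA_Z = 1.96


@dataclass(frozen=True)
class AgreementSummary:
    bias: float                 # mean difference, mL
    sd_diff: float
    loa_lower: float
    loa_upper: float
    fraction_within: float
    n_pairs: int

    def to_json(self) -> str:
        return json.dumps({
            "bias": self.bias, "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower, "loa_upper": self.loa_upper,
            "fraction_within": self.fraction_within, "n_pairs": self.n_pairs,
        }, indent=2)


def bland_altman(
    values_a, values_b, direction: str = "b_minus_a"
) -> tuple[AgreementSummary, pd.DataFrame]:
    """Summary statistics and plot-ready (mean, difference) table.

    With identical inputs the SD of differences is zero; the degenerate
    limits collapse onto the bias and the within-limits fraction is 1 by
    convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if direction == "b_minus_a":
        diff = b - a
    elif direction == "a_minus_b":
        diff = a - b
    else:
        raise ValueError(f"unknown direction {direction!r}")
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - LOA_Z * sd, bias + LOA_Z * sd
    if sd == 0:
        frac = 1.0
    else:
        frac = float(((diff >= lo) & (diff <= hi)).mean())
    summary = AgreementSummary(
        bias=bias, sd_diff=sd, loa_lower=float(lo), loa_upper=float(hi),
        fraction_within=frac, n_pairs=len(a),
    )
    plot_data = pd.DataFrame({"mean": mean, "difference": diff})
    return summary, plot_data
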