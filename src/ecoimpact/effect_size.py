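"""Small-sample-corrected standardized mean differences (Hedges' g).

Each response variable measured on treated and control replicate groups is
summarised as a standardized mean difference

    g = J * (mean_T - mean_C) / s_p

with pooled standard deviation

    s_p = sqrt(((n_T - 1) s_T^2 + (n_C - 1) s_C^2) / (n_T + n_C - 2))

and the small-sample bias correction J = 1 - 3 / (4 m - 1), m = n_T + n_C - 2.
The large-sample variance of g is

    var(g) = (n_T + n_C) / (n_T n_C) + g^2 / (2 (n_T + n_C))

and 95% confidence intervals use the normal quantile, g +/- 1.96 sqrt(var(g)).
The sign convention is treated minus control: positive g means the treated
group mean exceeds the control mean (on the analysis scale, i.e. after any
log10 transform configured for that variable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectSizeEstimate",
    "hedges_g",
    "effect_size_table",
    "estimates_to_frame",
    "write_effect_sizes",
]

#: normal 97.5% quantile used for all 95% confidence intervals
Z95 = 1.96

MEASUREMENT_COLUMNS = (
    "sample_id",
    "treatment",
    "timepoint",
    "replicate",
    "variable",
    "value",
)


@dataclass(frozen=True)
class EffectSizeEstimate:
    """Hedges' g for one (treatment, timepoint, variable) against control."""

    treatment: str
    timepoint: str
    variable: str
    g: float
    var_g: float
    ci_low: float
    ci_high: float
    n_treated: int
    n_control: int
    transform_applied: str = "none"


def hedges_g(
    control_values: Sequence[float],
    treated_values: Sequence[float],
    *,
    treatment: str = "",
    timepoint: str = "",
    variable: str = "",
    transform_applied: str = "none",
) -> EffectSizeEstimate:
    """Hedges' g of ``treated_values`` relative to ``control_values``.

    Both groups need at least two finite values. A pooled standard deviation
    of zero is accepted only in the degenerate no-effect case (equal means),
    where g = 0 and var(g) keeps the sample-size term only.
    """
    c = np.asarray(control_values, dtype=float)
    t = np.asarray(treated_values, dtype=float)
    if c.size < 2 or t.size < 2:
        raise ValueError("insufficient replicates: need >=2 values per group")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite values in input groups")

    n_c, n_t = int(c.size), int(t.size)
    m = n_t + n_c - 2
    s2_p = ((n_t - 1) * t.var(ddof=1) + (n_c - 1) * c.var(ddof=1)) / m
    j = 1.0 - 3.0 / (4.0 * m - 1.0)
    n_term = (n_t + n_c) / (n_t * n_c)

    if s2_p == 0.0:
        if t.mean() != c.mean():
            raise ValueError("zero pooled variance with unequal means")
        g = 0.0
        var_g = n_term
    else:
        g = float(j * (t.mean() - c.mean()) / math.sqrt(s2_p))
        var_g = n_term + g * g / (2.0 * (n_t + n_c))

    half = Z95 * math.sqrt(var_g)
    return EffectSizeEstimate(
        treatment=treatment,
        timepoint=timepoint,
        variable=variable,
        g=g,
        var_g=var_g,
        ci_low=g - half,
        ci_high=g + half,
        n_treated=n_t,
        n_control=n_c,
        transform_applied=transform_applied,
    )


def _group_values(
    sub: pd.DataFrame, transform: str, treatment: str, variable: str
) -> np.ndarray:
    vals = sub["value"].to_numpy(dtype=float)
    if transform == "log10":
        if np.any(vals <= 0):
            bad = sub.loc[sub["value"] <= 0, "sample_id"].iloc[0]
            raise ValueError(
                f"non-positive value under log10 transform for variable "
                f"{variable!r} in sample {bad!r}"
            )
        vals = np.log10(vals)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r} for {variable!r}")
    return vals


def effect_size_table(
    measurements: pd.DataFrame,
    control_label: str,
    variable_set: Sequence[str],
    transform_map: Mapping[str, str] | None = None,
) -> list[EffectSizeEstimate]:
    """One :class:`EffectSizeEstimate` per (treatment != control, timepoint,
    variable), ordered lexicographically.

    ``measurements`` is a long-format table with the columns
    ``sample_id treatment timepoint replicate variable value``. Values are
    log10-transformed before g when ``transform_map`` maps the variable to
    ``"log10"``.
    """
    transform_map = dict(transform_map or {})
    missing_cols = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing_cols:
        raise ValueError(f"measurement table missing columns: {sorted(missing_cols)}")

    treatments = sorted(set(measurements["treatment"]) - {control_label})
    timepoints = sorted(set(measurements["timepoint"]))
    if control_label not in set(measurements["treatment"]):
        raise ValueError(f"control label {control_label!r} absent from table")

    grouped = {
        key: sub
        for key, sub in measurements.groupby(["treatment", "timepoint", "variable"])
    }
    present = set(zip(measurements["treatment"], measurements["timepoint"]))
    out: list[EffectSizeEstimate] = []
    for treatment in treatments:
        for timepoint in timepoints:
            if (control_label, timepoint) not in present:
                raise ValueError(f"missing control group at timepoint {timepoint!r}")
            for variable in sorted(variable_set):
                transform = transform_map.get(variable, "none")
                ctrl = grouped.get((control_label, timepoint, variable))
                trt = grouped.get((treatment, timepoint, variable))
                if ctrl is None or ctrl.empty:
                    raise ValueError(
                        f"variable {variable!r} absent for control at {timepoint!r}"
                    )
                if trt is None or trt.empty:
                    raise ValueError(
                        f"variable {variable!r} absent for treatment {treatment!r}"
                    )
                out.append(
                    hedges_g(
                        _group_values(ctrl, transform, control_label, variable),
                        _group_values(trt, transform, treatment, variable),
                        treatment=treatment,
                        timepoint=timepoint,
                        variable=variable,
                        transform_applied=transform,
                    )
                )
    return out


def estimates_to_frame(estimates: Sequence[EffectSizeEstimate]) -> pd.DataFrame:
    """Tabulate estimates with the standard output columns."""
    return pd.DataFrame(
        [
            {
                "treatment": e.treatment,
                "timepoint": e.timepoint,
                "variable": e.variable,
                "g": e.g,
                "var_g": e.var_g,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_treated": e.n_treated,
                "n_control": e.n_control,
                "transform": e.transform_applied,
            }
            for e in estimates
        ]
    )


def write_effect_sizes(estimates: Sequence[EffectSizeEstimate], path) -> None:
    """Write the tab-separated effect-size table."""
    estimates_to_frame(estimates).to_csv(path, sep="\t", index=False)
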