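"""Ecosystem Aggregated Impact (EAI).

The EAI of a treatment at a timepoint is the sum over the monitored response
variables of the absolute value of Hedges' g against the control,

    EAI = sum_v |g_v|,    var(EAI) = sum_v var(g_v),

with a 95% CI of EAI +/- 1.96 sqrt(var(EAI)). Summing the per-variable
variances is valid for approximately normally distributed effect estimates;
the folded-normal variance of |g| is available behind an off-by-default
option for sensitivity analysis. Treatments whose 95% CIs do not overlap are
considered significantly different, and a compact letter display encodes the
overlap relation: two treatments share a letter if and only if their closed
intervals intersect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effect_size import Z95, EffectSizeEstimate

__all__ = ["EAISummary", "aggregate_eai", "eai_table", "assign_letters", "eai_report"]


@dataclass(frozen=True)
class EAISummary:
    treatment: str
    timepoint: str
    eai: float
    var_eai: float
    ci_low: float
    ci_high: float
    n_variables: int
    letter: str = ""


def _folded_moments(g: float, var_g: float) -> tuple[float, float]:
    # mean/variance of |X| for X ~ N(g, var_g)
    sd = math.sqrt(var_g)
    if sd == 0.0:
        return abs(g), 0.0
    mean = sd * math.sqrt(2.0 / math.pi) * math.exp(-g * g / (2 * var_g)) + g * (
        1.0 - 2.0 * norm.cdf(-g / sd)
    )
    return mean, g * g + var_g - mean * mean


def aggregate_eai(
    estimates: Sequence[EffectSizeEstimate],
    variable_set: Sequence[str],
    *,
    folded_variance: bool = False,
) -> EAISummary:
    """Aggregate per-variable effect sizes for one treatment x timepoint.

    ``estimates`` must cover exactly the variables in ``variable_set`` and
    share a single treatment and timepoint. ``folded_variance=True`` replaces
    the published sum-of-var(g) by the folded-normal variance of each |g|.
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    treatments = {e.treatment for e in estimates}
    timepoints = {e.timepoint for e in estimates}
    if len(treatments) != 1 or len(timepoints) != 1:
        raise ValueError(
            f"mixed treatments/timepoints in input: {sorted(treatments)} x "
            f"{sorted(timepoints)}"
        )
    seen = [e.variable for e in estimates]
    dupes = {v for v in seen if seen.count(v) > 1}
    if dupes:
        raise ValueError(f"duplicated variable(s): {sorted(dupes)}")
    missing = set(variable_set) - set(seen)
    extra = set(seen) - set(variable_set)
    if missing or extra:
        raise ValueError(
            f"estimates do not match variable set; missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )

    ordered = sorted(estimates, key=lambda e: e.variable)  # order-independent sums
    eai = float(sum(abs(e.g) for e in ordered))
    if folded_variance:
        var_eai = float(sum(_folded_moments(e.g, e.var_g)[1] for e in ordered))
    else:
        var_eai = float(sum(e.var_g for e in ordered))
    half = Z95 * math.sqrt(var_eai)
    return EAISummary(
        treatment=treatments.pop(),
        timepoint=timepoints.pop(),
        eai=eai,
        var_eai=var_eai,
        ci_low=eai - half,
        ci_high=eai + half,
        n_variables=len(seen),
    )


def eai_table(
    estimates: Sequence[EffectSizeEstimate],
    variable_set: Sequence[str],
    *,
    letters_within_timepoint: bool = True,
    folded_variance: bool = False,
) -> list[EAISummary]:
    """Aggregate a full effect-size table into one EAI per treatment x
    timepoint, with significance letters assigned within each timepoint by
    default (set ``letters_within_timepoint=False`` to compare all cells)."""
    cells: dict[tuple[str, str], list[EffectSizeEstimate]] = {}
    for e in estimates:
        cells.setdefault((e.treatment, e.timepoint), []).append(e)
    summaries = [
        aggregate_eai(v, variable_set, folded_variance=folded_variance)
        for _, v in sorted(cells.items())
    ]
    if letters_within_timepoint:
        out: list[EAISummary] = []
        for tp in sorted({s.timepoint for s in summaries}):
            out.extend(assign_letters([s for s in summaries if s.timepoint == tp]))
        return sorted(out, key=lambda s: (s.timepoint, s.treatment))
    return sorted(assign_letters(summaries), key=lambda s: (s.timepoint, s.treatment))


def _letter(i: int) -> str:
    # a..z, then aa, ab, ...
    s = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        s = chr(ord("a") + r) + s
    return s


def assign_letters(summaries: Sequence[EAISummary]) -> list[EAISummary]:
    """Populate ``letter`` so two summaries share a letter iff their closed
    95% CIs overlap.

    Closed intervals on a line have the Helly property: any set of pairwise
    intersecting intervals has a common point, so the maximal cliques of the
    overlap graph are exactly the maximal sets of intervals covering some
    interval start. The sweep below collects, for each interval, the set of
    intervals covering its lower bound, absorbs subsets, and letters the
    surviving maximal sets in order of their smallest member EAI.
    """
    if not summaries:
        raise ValueError("no summaries to letter")
    order = sorted(range(len(summaries)), key=lambda i: summaries[i].eai)
    lows = [summaries[i].ci_low for i in order]
    highs = [summaries[i].ci_high for i in order]
    n = len(order)

    cliques: list[frozenset[int]] = []
    for i in range(n):
        group = frozenset(
            j for j in range(n) if lows[j] <= lows[i] <= highs[j]
        )
        # insert, absorbing any clique contained in another
        if any(group <= c for c in cliques):
            continue
        cliques = [c for c in cliques if not (c <= group)] + [group]

    cliques.sort(key=lambda c: min(c))
    letters_by_pos: dict[int, list[str]] = {i: [] for i in range(n)}
    for k, clique in enumerate(cliques):
        for i in clique:
            letters_by_pos[i].append(_letter(k))

    out = list(summaries)
    for pos, idx in enumerate(order):
        out[idx] = replace(summaries[idx], letter="".join(sorted(letters_by_pos[pos])))
    return out


def summaries_to_frame(summaries: Sequence[EAISummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "treatment": s.treatment,
                "timepoint": s.timepoint,
                "eai": s.eai,
                "var_eai": s.var_eai,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "n_variables": s.n_variables,
                "letter": s.letter,
            }
            for s in summaries
        ]
    )


def eai_report(summaries: Sequence[EAISummary], path) -> None:
    """Write the tab-separated EAI table, rows sorted by timepoint then EAI
    descending, numeric columns at 6 significant digits."""
    if not summaries:
        raise ValueError("no summaries to report")
    df = summaries_to_frame(summaries).sort_values(
        ["timepoint", "eai"], ascending=[True, False]
    )
    for col in ("eai", "var_eai", "ci_low", "ci_high"):
        df[col] = df[col].map(lambda x: float(f"{x:.6g}"))
    df.to_csv(path, sep="\t", index=False)
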