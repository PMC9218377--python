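"""Check-relative yield ranking and micronutrient threshold screening."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import pandas as pd


class SelectionError(ValueError):
    pass


@dataclass
class SelectionReport:
    """Ranked check-relative gains and/or nutrient screen results."""

    ranked: pd.DataFrame = field(default_factory=pd.DataFrame)
    best_check: str | None = None
    best_check_value: float | None = None
    screens: dict[str, list[str]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    excluded: dict[str, list[str]] = field(default_factory=dict)


def _clean(values: Mapping[str, float]) -> dict[str, float]:
    return {
        g: float(v)
        for g, v in values.items()
        if v is not None and not (isinstance(v, float) and math.isnan(v))
    }


def percent_gain_over_best_check(
    values: Mapping[str, float] | pd.Series,
    checks: Sequence[str],
    direction: str = "max",
) -> SelectionReport:
    """Rank genotypes by trait value and express each as percent gain over the
    best check.

    ``direction="max"`` (benefit traits, e.g. yield) takes the maximal check
    as best; ``"min"`` (cost traits, e.g. earliness) the minimal, with gains
    sign-flipped so that better-than-check stays positive.
    """
    if direction not in ("max", "min"):
        raise SelectionError("direction must be 'max' or 'min'")
    vals = _clean(dict(values))
    check_vals = {c: vals[c] for c in checks if c in vals}
    if not check_vals:
        raise SelectionError("no check values available")
    if direction == "max":
        best_check = max(check_vals, key=lambda c: (check_vals[c], c))
    else:
        best_check = min(check_vals, key=lambda c: (check_vals[c], c))
    best = check_vals[best_check]
    if best == 0:
        raise SelectionError("best check value is zero; gains undefined")

    sign = 1.0 if direction == "max" else -1.0
    frame = pd.DataFrame(
        {"genotype": list(vals), "value": [vals[g] for g in vals]}
    )
    frame["pct_gain"] = sign * 100.0 * (frame["value"] - best) / abs(best)
    ascending = direction == "min"
    frame = frame.sort_values(
        ["value", "genotype"], ascending=[ascending, True]
    ).reset_index(drop=True)
    frame["rank"] = range(1, len(frame) + 1)
    return SelectionReport(
        ranked=frame[["genotype", "value", "rank", "pct_gain"]],
        best_check=best_check,
        best_check_value=best,
    )


def rank_and_select(report: SelectionReport, min_gain: float) -> list[str]:
    """Genotypes with gain >= min_gain (inclusive), best first; ties broken by
    genotype identifier."""
    if report.ranked.empty:
        raise SelectionError("report carries no ranked gains")
    hits = report.ranked[report.ranked["pct_gain"] >= min_gain]
    hits = hits.sort_values(["pct_gain", "genotype"], ascending=[False, True])
    return hits["genotype"].tolist()


def nutrient_screen(
    fe: Mapping[str, float] | pd.Series,
    zn: Mapping[str, float] | pd.Series,
    fe_min: float = 60.0,
    zn_min: float = 32.0,
) -> SelectionReport:
    """Strict-inequality screens: pass_fe = {Fe > fe_min}, pass_zn =
    {Zn > zn_min}, pass_either their union. Genotypes missing a value are
    excluded from that screen and listed under ``excluded``."""
    fe_vals, zn_vals = _clean(dict(fe)), _clean(dict(zn))
    if not fe_vals and not zn_vals:
        raise SelectionError("no nutrient values available")
    universe = sorted(set(dict(fe)) | set(dict(zn)))
    pass_fe = sorted(g for g, v in fe_vals.items() if v > fe_min)
    pass_zn = sorted(g for g, v in zn_vals.items() if v > zn_min)
    pass_either = sorted(set(pass_fe) | set(pass_zn))
    return SelectionReport(
        screens={"pass_fe": pass_fe, "pass_zn": pass_zn, "pass_either": pass_either},
        thresholds={"fe_min": fe_min, "zn_min": zn_min},
        excluded={
            "fe": sorted(set(universe) - set(fe_vals)),
            "zn": sorted(set(universe) - set(zn_vals)),
        },
    )
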