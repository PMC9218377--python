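"""Variance components and derived selection-genetics statistics.

From a combined two-way ANOVA of adjusted means: GV = (MS_G - MS_GxE)/n_env
(truncated at zero), EV = MS_GxE, PV = GV + EV. Derived quantities: genotypic,
phenotypic and environmental coefficients of variation, broad-sense
heritability, and expected genetic advance under truncation selection with
standardized differential k (2.056 for the top 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from augtrial.augmented_design import AnovaTable

DEFAULT_K = 2.056

#: classification scales with continuous boundaries (low <= a < moderate <= b < high)
_SCALES = {
    "cv": (10.0, 20.0, ("low", "moderate", "high")),
    "h2": (30.0, 60.0, ("low", "medium", "high")),
    "ga_pct": (10.0, 20.0, ("low", "moderate", "high")),
}


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    trait: str
    PV: float
    GV: float
    EV: float
    mean: float
    n_env: int
    negative_gv_truncated: bool = False

    def __post_init__(self) -> None:
        if min(self.PV, self.GV, self.EV) < 0:
            raise ParameterError(f"{self.trait}: variance components must be >= 0")
        if not np.isclose(self.PV, self.GV + self.EV):
            raise ParameterError(f"{self.trait}: PV must equal GV + EV")


class CoefficientsOfVariation(NamedTuple):
    GCV: float
    PCV: float
    ECV: float


@dataclass
class GeneticParameterSet:
    """Per-trait bundle of the derived statistics plus class labels."""

    trait: str
    mean: float
    PV: float
    GV: float
    EV: float
    GCV: float
    PCV: float
    ECV: float
    H2: float
    GA: float
    GA_pct: float
    k: float = DEFAULT_K
    classes: dict[str, str] = field(default_factory=dict)


def estimate_variance_components(combined: AnovaTable, n_env: int) -> VarianceComponents:
    """Method-of-moments components from the combined ANOVA mean squares.

    A negative genotypic estimate (MS_G < MS_GxE) is truncated to zero and
    flagged rather than raised.
    """
    try:
        ms_g = combined.ms("Genotype")
        ms_ge = combined.ms("Genotype x Environment")
    except KeyError as exc:
        raise ParameterError(
            "combined ANOVA lacks Genotype / Genotype x Environment rows"
        ) from exc
    if n_env < 1:
        raise ParameterError("n_env must be >= 1")
    gv = (ms_g - ms_ge) / n_env
    truncated = gv < 0
    gv = max(gv, 0.0)
    ev = ms_ge
    mean = combined.metadata.get("grand_mean", np.nan)
    return VarianceComponents(
        trait=str(combined.metadata.get("trait", "")),
        PV=gv + ev,
        GV=gv,
        EV=ev,
        mean=float(mean),
        n_env=n_env,
        negative_gv_truncated=bool(truncated),
    )


def coefficients_of_variation(vc: VarianceComponents) -> CoefficientsOfVariation:
    """GCV/PCV/ECV = 100 * sqrt(component) / mean, in percent."""
    if not vc.mean > 0:
        raise ParameterError(f"{vc.trait}: mean must be > 0 for CV")
    return CoefficientsOfVariation(
        GCV=100.0 * np.sqrt(vc.GV) / vc.mean,
        PCV=100.0 * np.sqrt(vc.PV) / vc.mean,
        ECV=100.0 * np.sqrt(vc.EV) / vc.mean,
    )


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """H2 = 100 * GV / PV, in percent."""
    if not vc.PV > 0:
        raise ParameterError(f"{vc.trait}: PV must be > 0 for heritability")
    return 100.0 * vc.GV / vc.PV


def genetic_advance(
    vc: VarianceComponents, k: float = DEFAULT_K
) -> tuple[float, float]:
    """GA = (GV/PV) * sqrt(PV) * k (heritability as a fraction times the
    phenotypic standard deviation times the selection differential), and
    GA% = 100 * GA / mean."""
    if vc.PV < 0:
        raise ParameterError(f"{vc.trait}: PV must be >= 0")
    ga = (vc.GV / vc.PV) * np.sqrt(vc.PV) * k if vc.PV > 0 else 0.0
    if not vc.mean > 0:
        raise ParameterError(f"{vc.trait}: mean must be > 0 for GA%")
    return float(ga), float(100.0 * ga / vc.mean)


def classify_parameter(statistic: str, value: float) -> str:
    """Label a percentage on the conventional low/moderate(medium)/high scale.

    Boundaries are continuous: low <= 10 < moderate <= 20 < high for CV and
    GA%, low <= 30 < medium <= 60 < high for heritability.
    """
    if statistic not in _SCALES:
        raise ParameterError(f"unknown statistic {statistic!r}; expected {list(_SCALES)}")
    if value < 0:
        raise ParameterError(f"{statistic}: value must be >= 0, got {value}")
    low_cap, mid_cap, labels = _SCALES[statistic]
    if value <= low_cap:
        return labels[0]
    if value <= mid_cap:
        return labels[1]
    return labels[2]


def genetic_parameter_set(
    vc: VarianceComponents, k: float = DEFAULT_K
) -> GeneticParameterSet:
    gcv, pcv, ecv = coefficients_of_variation(vc)
    h2 = broad_sense_heritability(vc)
    ga, ga_pct = genetic_advance(vc, k)
    classes = {
        "GCV": classify_parameter("cv", gcv),
        "PCV": classify_parameter("cv", pcv),
        "ECV": classify_parameter("cv", ecv),
        "H2": classify_parameter("h2", h2),
        "GA_pct": classify_parameter("ga_pct", ga_pct),
    }
    return GeneticParameterSet(
        trait=vc.trait, mean=vc.mean, PV=vc.PV, GV=vc.GV, EV=vc.EV,
        GCV=gcv, PCV=pcv, ECV=ecv, H2=h2, GA=ga, GA_pct=ga_pct, k=k,
        classes=classes,
    )


def genetic_parameter_table(
    components: Sequence[VarianceComponents], k: float = DEFAULT_K
) -> pd.DataFrame:
    """One row per trait in the conventional report layout (Mean, PV, GV, EV,
    GCV, PCV, ECV, H2, GA, GA%) plus class-label columns."""
    rows = []
    for vc in components:
        ps = genetic_parameter_set(vc, k)
        rows.append(
            {
                "trait": ps.trait, "mean": ps.mean, "PV": ps.PV, "GV": ps.GV,
                "EV": ps.EV, "GCV": ps.GCV, "PCV": ps.PCV, "ECV": ps.ECV,
                "H2": ps.H2, "GA": ps.GA, "GA_pct": ps.GA_pct,
                "GCV_class": ps.classes["GCV"], "PCV_class": ps.classes["PCV"],
                "ECV_class": ps.classes["ECV"], "H2_class": ps.classes["H2"],
                "GA_pct_class": ps.classes["GA_pct"],
            }
        )
    return pd.DataFrame(rows)
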