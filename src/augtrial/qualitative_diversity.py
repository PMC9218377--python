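"""Shannon-Weaver diversity, equitability and heterogeneity tests for
qualitative descriptors.

H' = -sum(p_i ln p_i) over observed classes (0 ln 0 = 0). Equitability
E_H = H'/ln(S); by default S is the number of accessions scored (the
convention matching germplasm-catalogue reports), with the textbook
S = number of declared categories as an explicit option. The chi-square
heterogeneity test uses an equiprobable null over declared categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from augtrial.trial_data import TrialDataset

EQUITABILITY_BASES = ("accessions", "categories")


class DiversityError(ValueError):
    pass


@dataclass
class CategoryDistribution:
    """Observed per-category counts for one qualitative trait."""

    trait: str
    counts: dict[str, int]
    declared_categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise DiversityError(f"{self.trait}: negative category count")
        extra = sorted(set(self.counts) - set(self.declared_categories))
        if extra:
            raise DiversityError(f"{self.trait}: undeclared categories {extra}")

    @property
    def n_total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def proportions(self) -> dict[str, float]:
        n = self.n_total
        if n == 0:
            raise DiversityError(f"{self.trait}: empty distribution")
        return {cat: cnt / n for cat, cnt in self.counts.items()}


@dataclass
class DiversitySummary:
    trait: str
    H_prime: float
    E_H: float
    Hmax: float
    S_basis: str
    chi2: float
    df: int
    p: float
    proportions: dict[str, float]


def genotype_consensus(data: TrialDataset, trait: str) -> pd.Series:
    """Per-genotype modal category across plots/locations; ties broken by
    the first-declared category."""
    spec = data.traits[trait]
    if spec.kind != "qualitative":
        raise DiversityError(f"trait {trait!r} is not qualitative")
    obs = data.observations
    sub = obs.loc[(obs["trait"] == trait) & obs["value"].notna(), ["genotype", "value"]]
    order = {cat: i for i, cat in enumerate(spec.categories)}

    def modal(values: pd.Series) -> str:
        counts = values.value_counts()
        top = counts.max()
        tied = sorted(counts[counts == top].index, key=lambda c: order[c])
        return tied[0]

    return sub.groupby("genotype")["value"].agg(modal)


def category_proportions(data: TrialDataset, trait: str) -> CategoryDistribution:
    """Category counts over genotypes with a non-missing consensus value."""
    consensus = genotype_consensus(data, trait)
    if consensus.empty:
        raise DiversityError(f"trait {trait!r}: all values missing")
    counts = consensus.value_counts().to_dict()
    return CategoryDistribution(trait, counts, data.traits[trait].categories)


def shannon_index(dist: CategoryDistribution | Iterable[float]) -> float:
    """H' = -sum over p_i > 0 of p_i ln p_i (natural log)."""
    if isinstance(dist, CategoryDistribution):
        p = np.array(list(dist.proportions.values()), dtype=float)
    else:
        p = np.asarray(list(dist), dtype=float)
        if (p < 0).any():
            raise DiversityError("proportions must be non-negative")
        total = p.sum()
        if total <= 0:
            raise DiversityError("proportions must sum to a positive value")
        p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def equitability(h_prime: float, s: int, basis: str = "accessions") -> float:
    """E_H = H'/ln(S); S is the accession count (default) or the category
    count depending on ``basis``."""
    if basis not in EQUITABILITY_BASES:
        raise DiversityError(f"basis must be one of {EQUITABILITY_BASES}")
    if s < 2:
        raise DiversityError(f"S must be >= 2, got {s}")
    return float(h_prime / np.log(s))


def chi_square_uniformity(dist: CategoryDistribution) -> tuple[float, int, float]:
    """Chi-square against the equiprobable null over declared categories."""
    s = len(dist.declared_categories)
    if s < 2:
        raise DiversityError(f"{dist.trait}: need >=2 declared categories")
    if dist.n_total <= 0:
        raise DiversityError(f"{dist.trait}: empty distribution")
    observed = np.array(
        [dist.counts.get(cat, 0) for cat in dist.declared_categories], dtype=float
    )
    chi2, p = stats.chisquare(observed)
    return float(chi2), s - 1, float(p)


def diversity_table(
    data: TrialDataset, basis: str = "accessions"
) -> tuple[list[DiversitySummary], float]:
    """One :class:`DiversitySummary` per qualitative trait plus the unweighted
    mean of the per-trait H' values."""
    traits = data.traits_of_kind("qualitative")
    if not traits:
        raise DiversityError("dataset has no qualitative traits")
    summaries = []
    for trait in traits:
        dist = category_proportions(data, trait)
        h = shannon_index(dist)
        s = dist.n_total if basis == "accessions" else len(dist.declared_categories)
        e_h = equitability(h, s, basis) if s >= 2 else 0.0
        chi2, df, p = chi_square_uniformity(dist)
        summaries.append(
            DiversitySummary(
                trait=trait,
                H_prime=h,
                E_H=e_h,
                Hmax=float(np.log(s)),
                S_basis=basis,
                chi2=chi2,
                df=df,
                p=p,
                proportions=dist.proportions,
            )
        )
    mean_h = float(np.mean([s.H_prime for s in summaries]))
    return summaries, mean_h


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def diversity_frame(summaries: Sequence[DiversitySummary], mean_h: float) -> pd.DataFrame:
    """Flat CSV-ready layout: one row per trait-category with per-trait index
    columns repeated, plus a trailing mean row."""
    rows = []
    for s in summaries:
        for cat, prop in s.proportions.items():
            rows.append(
                {
                    "trait": s.trait, "category": cat,
                    "proportion_pct": 100.0 * prop,
                    "H_prime": s.H_prime, "E_H": s.E_H, "df": s.df,
                    "chi2": s.chi2, "significance": significance_stars(s.p),
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["mean_H_prime"] = mean_h
    return frame
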