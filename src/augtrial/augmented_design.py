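"""Check-based block adjustment and ANOVA for augmented block designs.

Unreplicated test entries are corrected by the deviation of their block's
check mean from the grand check mean (the classical augmented-RCBD
estimator); replicated checks provide both the block information and the
intra-block error. A combined across-location analysis decomposes the
genotype-by-location table of adjusted means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from augtrial.trial_data import TrialDataset

ADJUSTMENT_METHOD = "check-mean block adjustment (augmented RCBD)"


class DesignError(ValueError):
    """Raised when the layout cannot support the requested analysis."""


@dataclass(frozen=True)
class BlockAdjustment:
    location: str
    block: str
    adjustment: float
    n_checks_used: int


@dataclass
class AdjustedMeansTable:
    """Adjusted genotype means per location plus their across-location pool.

    ``per_location``: MultiIndex (genotype, location) x trait.
    ``pooled``: genotype x trait, arithmetic mean over available locations.
    """

    per_location: pd.DataFrame
    pooled: pd.DataFrame
    roles: pd.Series
    method: str = ADJUSTMENT_METHOD

    def location_slice(self, location: str) -> pd.DataFrame:
        return self.per_location.xs(location, level="location")

    def tests_matrix(self, trait: str) -> pd.DataFrame:
        """Genotype x location matrix of adjusted means for test entries
        present at every location (others dropped)."""
        tests = self.roles[self.roles == "test"].index
        wide = (
            self.per_location[trait]
            .unstack("location")
            .reindex(tests)
        )
        return wide.dropna(axis=0, how="any")


@dataclass
class AnovaTable:
    """Ordered (source, df, SS, MS, F, p) rows with a designated error row."""

    rows: pd.DataFrame
    error_row: str
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, source: str) -> pd.Series:
        hit = self.rows[self.rows["source"] == source]
        if hit.empty:
            raise KeyError(source)
        return hit.iloc[0]

    def ms(self, source: str) -> float:
        return float(self[source]["MS"])

    def df(self, source: str) -> int:
        return int(self[source]["df"])


# -- block adjustments ---------------------------------------------------------


def compute_block_adjustments(
    data: TrialDataset, location: str, trait: str
) -> list[BlockAdjustment]:
    """Per-block adjustment = block check mean - grand check mean (grand mean
    taken over all check plot values at the location). Blocks with no check
    value get adjustment 0 and a warning."""
    sub = data.numeric_slice(trait, location)
    checks = sub[(sub["role"] == "check") & sub["value"].notna()]
    if checks.empty or checks["genotype"].nunique() < 2 or len(checks) < 2:
        raise DesignError(
            f"trait {trait!r} at {location!r}: need >=2 check values for adjustment"
        )
    grand = checks["value"].mean()
    by_block = checks.groupby("block")["value"].agg(["mean", "count"])
    out: list[BlockAdjustment] = []
    for block in data.blocks(location):
        if block in by_block.index:
            row = by_block.loc[block]
            out.append(
                BlockAdjustment(location, block, float(row["mean"] - grand), int(row["count"]))
            )
        else:
            warnings.warn(
                f"block {block!r} at {location!r} has no check values for {trait!r}; "
                "adjustment set to 0",
                stacklevel=2,
            )
            out.append(BlockAdjustment(location, block, 0.0, 0))
    return out


def adjust_test_entries(
    data: TrialDataset, location: str, traits: Sequence[str] | None = None
) -> pd.DataFrame:
    """Genotype x trait adjusted values for one location.

    Test entries: observed minus their block's adjustment. Check entries: raw
    arithmetic mean over blocks. Missing observations stay missing.
    """
    if traits is None:
        traits = data.traits_of_kind("quantitative", "count")
    frames: dict[str, pd.Series] = {}
    for trait in traits:
        sub = data.numeric_slice(trait, location)
        if sub.empty:
            continue
        adjustments = {
            adj.block: adj.adjustment
            for adj in compute_block_adjustments(data, location, trait)
        }
        tests = sub[sub["role"] == "test"].copy()
        tests["adjusted"] = tests["value"] - tests["block"].map(adjustments)
        test_series = tests.set_index("genotype")["adjusted"]
        check_series = (
            sub[sub["role"] == "check"].groupby("genotype")["value"].mean()
        )
        frames[trait] = pd.concat([test_series, check_series])
    out = pd.DataFrame(frames)
    out.index.name = "genotype"
    return out.sort_index()


def adjusted_means(
    data: TrialDataset, traits: Sequence[str] | None = None
) -> AdjustedMeansTable:
    """Adjust every location and pool by arithmetic mean over locations."""
    locations = data.locations
    pieces = []
    for loc in locations:
        frame = adjust_test_entries(data, loc, traits)
        frame = frame.assign(location=loc).set_index("location", append=True)
        pieces.append(frame)
    per_location = pd.concat(pieces).sort_index()
    pooled = per_location.groupby(level="genotype").mean().sort_index()
    roles = (
        data.observations.drop_duplicates("genotype")
        .set_index("genotype")["role"]
        .sort_index()
    )
    return AdjustedMeansTable(per_location, pooled, roles)


# -- least-squares helpers -----------------------------------------------------


def _dummy(labels: pd.Series) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(labels, sort=True)
    mat = np.zeros((len(labels), len(uniques)))
    mat[np.arange(len(labels)), codes] = 1.0
    return mat, len(uniques)


def _sse(y: np.ndarray, design: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


# -- single-location ANOVA -----------------------------------------------------


def anova_single_location(data: TrialDataset, location: str, trait: str) -> AnovaTable:
    """Augmented-design ANOVA at one location.

    Sequential (type-I) decomposition of y = mu + block + genotype fitted by
    least squares: Block is unadjusted, the genotype SS is adjusted for blocks
    and partitioned into Checks, Tests (among adjusted test values) and
    Tests-vs-Checks (remainder). Error is the intra-block residual of the
    replicated checks-by-blocks layout.
    """
    sub = data.numeric_slice(trait, location).dropna(subset=["value"])
    checks_present = sub.loc[sub["role"] == "check", "genotype"].nunique()
    if checks_present < 2:
        raise DesignError(
            f"trait {trait!r} at {location!r}: augmented ANOVA needs >=2 checks"
        )
    y = sub["value"].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    ones = np.ones((n, 1))
    blocks, b = _dummy(sub["block"])
    genos, g = _dummy(sub["genotype"])
    sse_mu = ss_total
    sse_block = _sse(y, np.hstack([ones, blocks]))
    sse_full = _sse(y, np.hstack([ones, blocks, genos]))
    ss_block = sse_mu - sse_block
    ss_geno = sse_block - sse_full

    # checks-only two-way layout supplies the intra-block error
    is_check = (sub["role"] == "check").to_numpy()
    yc = y[is_check]
    cb_blocks, b_used = _dummy(sub.loc[is_check, "block"])
    cb_checks, c = _dummy(sub.loc[is_check, "genotype"])
    onesc = np.ones((len(yc), 1))
    sse_cb_block = _sse(yc, np.hstack([onesc, cb_blocks]))
    ss_error = _sse(yc, np.hstack([onesc, cb_blocks, cb_checks]))
    ss_checks = sse_cb_block - ss_error
    df_error = len(yc) - (c - 1) - (b_used - 1) - 1

    # among adjusted test values
    adjustments = {
        adj.block: adj.adjustment
        for adj in compute_block_adjustments(data, location, trait)
    }
    tests = sub[sub["role"] == "test"]
    adj_vals = (tests["value"] - tests["block"].map(adjustments)).to_numpy(dtype=float)
    t = len(adj_vals)
    ss_tests = float(((adj_vals - adj_vals.mean()) ** 2).sum()) if t else 0.0
    ss_tvc = ss_geno - ss_checks - ss_tests

    if df_error <= 0:
        raise DesignError(
            f"trait {trait!r} at {location!r}: no intra-block error df "
            f"(checks {c} x blocks {b_used})"
        )
    ms_error = ss_error / df_error

    sources = [
        ("Block", b - 1, ss_block),
        ("Genotypes", g - 1, ss_geno),
        ("Checks", c - 1, ss_checks),
        ("Tests", max(t - 1, 0), ss_tests),
        ("Tests-vs-Checks", 1, ss_tvc),
    ]
    rows = []
    for source, df_s, ss in sources:
        ms = ss / df_s if df_s > 0 else np.nan
        # remainder partitions of a nonorthogonal layout can go negative;
        # no F is reported for them
        f_stat = ms / ms_error if df_s > 0 and ms_error > 0 and ss >= 0 else np.nan
        p = float(stats.f.sf(f_stat, df_s, df_error)) if np.isfinite(f_stat) else np.nan
        rows.append((source, df_s, ss, ms, f_stat, p))
    rows.append(("Error", df_error, ss_error, ms_error, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"])
    return AnovaTable(
        table,
        error_row="Error",
        metadata={
            "location": location,
            "trait": trait,
            "n_checks": c,
            "n_tests": t,
            "n_blocks": b,
            "error_term": "intra-block (checks x blocks)",
        },
    )


# -- combined across-location ANOVA --------------------------------------------


def combined_anova(
    adjusted: AdjustedMeansTable,
    error_pool: Sequence[AnovaTable],
    trait: str,
) -> AnovaTable:
    """Two-way decomposition of the genotype x location table of adjusted
    test-entry means: Genotype and Environment are tested against G x E,
    and G x E against the pooled intra-block error from the per-location
    analyses (one adjusted mean per cell, so G x E and error cannot be
    separated internally; this convention is recorded in metadata).

    Test entries missing at any location are dropped with a warning, mirroring
    complete-case pooling.
    """
    wide = adjusted.per_location[trait].unstack("location")
    tests = adjusted.roles[adjusted.roles == "test"].index
    wide = wide.reindex(wide.index.intersection(tests))
    if wide.shape[1] < 2:
        raise DesignError("combined ANOVA needs >=2 locations")
    complete = wide.dropna(axis=0, how="any")
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        warnings.warn(
            f"{len(dropped)} genotypes missing at some location dropped from "
            f"combined ANOVA for {trait!r}",
            stacklevel=2,
        )
    mat = complete.to_numpy(dtype=float)
    g, e = mat.shape
    if g < 2:
        raise DesignError("combined ANOVA needs >=2 genotypes present everywhere")
    grand = mat.mean()
    geno_means = mat.mean(axis=1)
    env_means = mat.mean(axis=0)
    ss_g = e * float(((geno_means - grand) ** 2).sum())
    ss_e = g * float(((env_means - grand) ** 2).sum())
    resid = mat - geno_means[:, None] - env_means[None, :] + grand
    ss_ge = float((resid**2).sum())

    df_g, df_e, df_ge = g - 1, e - 1, (g - 1) * (e - 1)
    ms_g, ms_e, ms_ge = ss_g / df_g, ss_e / df_e, ss_ge / df_ge

    f_g = ms_g / ms_ge if ms_ge > 0 else np.nan
    f_e = ms_e / ms_ge if ms_ge > 0 else np.nan
    p_g = float(stats.f.sf(f_g, df_g, df_ge)) if np.isfinite(f_g) else np.nan
    p_e = float(stats.f.sf(f_e, df_e, df_ge)) if np.isfinite(f_e) else np.nan

    pooled_ss = sum(tab["Error"]["SS"] for tab in error_pool)
    pooled_df = sum(tab["Error"]["df"] for tab in error_pool)
    if error_pool and pooled_df > 0:
        ms_pooled = pooled_ss / pooled_df
        f_ge = ms_ge / ms_pooled if ms_pooled > 0 else np.nan
        p_ge = (
            float(stats.f.sf(f_ge, df_ge, int(pooled_df)))
            if np.isfinite(f_ge)
            else np.nan
        )
    else:
        ms_pooled, f_ge, p_ge = np.nan, np.nan, np.nan

    rows = pd.DataFrame(
        [
            ("Genotype", df_g, ss_g, ms_g, f_g, p_g),
            ("Environment", df_e, ss_e, ms_e, f_e, p_e),
            ("Genotype x Environment", df_ge, ss_ge, ms_ge, f_ge, p_ge),
        ],
        columns=["source", "df", "SS", "MS", "F", "p"],
    )
    return AnovaTable(
        rows,
        error_row="Genotype x Environment",
        metadata={
            "trait": trait,
            "n_genotypes": g,
            "n_locations": e,
            "grand_mean": float(grand),
            "dropped_genotypes": dropped,
            "pooled_error_ms": float(ms_pooled) if np.isfinite(ms_pooled) else None,
            "pooled_error_df": int(pooled_df) if error_pool else 0,
            "note": (
                "test entries only; G and E tested against GxE; GxE tested "
                "against pooled intra-block error"
            ),
        },
    )
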