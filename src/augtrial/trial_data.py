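"""Data model, validation, I/O, and variable transforms for plot-level trial data.

The canonical on-disk representation is a long-format CSV with columns
``genotype, role, location, block, trait, value`` plus a trait-dictionary CSV
declaring each trait as quantitative, count, or qualitative. Everything
downstream consumes the :class:`TrialDataset` returned by the readers here.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TRAIT_KINDS = ("quantitative", "count", "qualitative")
TRANSFORMS = ("none", "sqrt")

LONG_COLUMNS = ["genotype", "role", "location", "block", "trait", "value"]


class TrialDataError(ValueError):
    """Raised for malformed files or contract violations in trial data."""


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of a single trait: its kind, units, categories and transform.

    Count traits default to a square-root transform; qualitative traits carry
    an ordered category list used for validation, consensus tie-breaking and
    chi-square expectations.
    """

    name: str
    kind: str
    units: str = ""
    categories: tuple[str, ...] = ()
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise TrialDataError(
                f"trait {self.name!r}: kind must be one of {TRAIT_KINDS}, got {self.kind!r}"
            )
        if self.transform not in TRANSFORMS:
            raise TrialDataError(
                f"trait {self.name!r}: transform must be one of {TRANSFORMS}"
            )
        if self.kind == "qualitative":
            if len(self.categories) < 2:
                raise TrialDataError(
                    f"qualitative trait {self.name!r} needs >=2 categories"
                )
            if self.transform != "none":
                raise TrialDataError(
                    f"qualitative trait {self.name!r} cannot carry a transform"
                )
        elif self.categories:
            raise TrialDataError(
                f"{self.kind} trait {self.name!r} must not declare categories"
            )

    @staticmethod
    def count(name: str, units: str = "", transform: str = "sqrt") -> "TraitSpec":
        return TraitSpec(name, "count", units, (), transform)


@dataclass
class ValidationIssue:
    severity: str  # "warning" | "error"
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.code}: {self.message}"


@dataclass
class ValidationReport:
    """Deterministic summary of structural problems in a :class:`TrialDataset`."""

    issues: list[ValidationIssue] = field(default_factory=list)
    missing_value_counts: dict[str, int] = field(default_factory=dict)
    single_location_entries: list[str] = field(default_factory=list)
    missing_genotypes: dict[str, list[str]] = field(default_factory=dict)
    blocks_missing_checks: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.issues

    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]


@dataclass
class TrialDataset:
    """Plot-level observations in long format plus the trait dictionary.

    ``observations`` columns: genotype, role, location, block, trait, value.
    Quantitative/count values are floats (NaN = missing); qualitative values
    are category labels (None/NaN = missing). Identifiers are case-sensitive
    opaque strings.
    """

    observations: pd.DataFrame
    traits: dict[str, TraitSpec]
    checks: tuple[str, ...]
    transformed: frozenset = frozenset()

    def __post_init__(self) -> None:
        obs = self.observations
        missing_cols = [c for c in LONG_COLUMNS if c not in obs.columns]
        if missing_cols:
            raise TrialDataError(f"observations missing columns {missing_cols}")
        unknown = sorted(set(obs["trait"]) - set(self.traits))
        if unknown:
            raise TrialDataError(f"traits not in dictionary: {unknown}")
        bad_roles = sorted(set(obs["role"]) - {"test", "check"})
        if bad_roles:
            raise TrialDataError(f"unknown roles {bad_roles}; expected test/check")
        for name, spec in self.traits.items():
            if spec.kind == "qualitative":
                vals = obs.loc[obs["trait"] == name, "value"].dropna()
                bad = sorted(set(vals.astype(str)) - set(spec.categories))
                if bad:
                    raise TrialDataError(
                        f"trait {name!r}: labels {bad} not in declared categories"
                    )
            else:
                vals = pd.to_numeric(
                    obs.loc[obs["trait"] == name, "value"], errors="coerce"
                )
                raw = obs.loc[obs["trait"] == name, "value"]
                if (vals.isna() & raw.notna()).any():
                    raise TrialDataError(f"trait {name!r}: non-numeric values present")
                if np.isinf(vals.to_numpy(dtype=float, na_value=np.nan)).any():
                    raise TrialDataError(f"trait {name!r}: non-finite values present")

    # -- convenience accessors -------------------------------------------------

    @property
    def locations(self) -> list[str]:
        return sorted(self.observations["location"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.observations["genotype"].unique())

    @property
    def test_genotypes(self) -> list[str]:
        obs = self.observations
        return sorted(obs.loc[obs["role"] == "test", "genotype"].unique())

    def blocks(self, location: str) -> list[str]:
        obs = self.observations
        return sorted(obs.loc[obs["location"] == location, "block"].unique())

    def traits_of_kind(self, *kinds: str) -> list[str]:
        return [n for n, s in self.traits.items() if s.kind in kinds]

    def numeric_slice(self, trait: str, location: str | None = None) -> pd.DataFrame:
        """Rows for one numeric trait with ``value`` coerced to float."""
        spec = self.traits[trait]
        if spec.kind == "qualitative":
            raise TrialDataError(f"trait {trait!r} is qualitative, not numeric")
        obs = self.observations
        mask = obs["trait"] == trait
        if location is not None:
            mask &= obs["location"] == location
        out = obs.loc[mask].copy()
        out["value"] = pd.to_numeric(out["value"])
        return out

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            self.observations.copy(),
            dict(self.traits),
            tuple(self.checks),
            frozenset(self.transformed),
        )


# -- trait dictionary I/O ------------------------------------------------------

DICT_COLUMNS = ["name", "kind", "units", "categories", "transform"]


def read_trait_dictionary(path: str | Path) -> dict[str, TraitSpec]:
    """Read a trait-dictionary CSV (columns name, kind, units, categories,
    transform; categories pipe-separated)."""
    path = Path(path)
    specs: dict[str, TraitSpec] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise TrialDataError(f"{path}: not a trait dictionary (no 'name' column)")
        for lineno, row in enumerate(reader, start=2):
            name = (row.get("name") or "").strip()
            if not name:
                raise TrialDataError(f"{path}:{lineno}: empty trait name")
            if name in specs:
                raise TrialDataError(f"{path}:{lineno}: duplicate trait {name!r}")
            kind = (row.get("kind") or "").strip()
            cats = tuple(
                c.strip() for c in (row.get("categories") or "").split("|") if c.strip()
            )
            transform = (row.get("transform") or "").strip()
            if not transform:
                transform = "sqrt" if kind == "count" else "none"
            specs[name] = TraitSpec(
                name, kind, (row.get("units") or "").strip(), cats, transform
            )
    return specs


def write_trait_dictionary(traits: Mapping[str, TraitSpec], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DICT_COLUMNS)
        for spec in traits.values():
            writer.writerow(
                [spec.name, spec.kind, spec.units, "|".join(spec.categories), spec.transform]
            )


# -- trial CSV I/O -------------------------------------------------------------


def _parse_value(raw: str, spec: TraitSpec, where: str):
    if raw is None or raw == "":
        return None
    if spec.kind == "qualitative":
        return raw
    try:
        val = float(raw)
    except ValueError as exc:
        raise TrialDataError(f"{where}: non-numeric value {raw!r} for {spec.name!r}") from exc
    if not math.isfinite(val):
        raise TrialDataError(f"{where}: non-finite value for {spec.name!r}")
    return val


def read_trial_csv(path: str | Path, dictionary_path: str | Path) -> TrialDataset:
    """Read a long-format trial CSV against a trait dictionary.

    Raises :class:`TrialDataError` naming the offending line for malformed
    rows and listing unknown traits; a check missing from a block is only a
    warning, surfaced later by :func:`validate_dataset`.
    """
    traits = read_trait_dictionary(dictionary_path)
    path = Path(path)
    records: list[dict] = []
    unknown: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrialDataError(f"{path}: empty file")
        missing = [c for c in LONG_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TrialDataError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in LONG_COLUMNS):
                raise TrialDataError(f"{path}:{lineno}: malformed row (short record)")
            trait = row["trait"]
            if trait not in traits:
                unknown.add(trait)
                continue
            value = _parse_value(row["value"], traits[trait], f"{path}:{lineno}")
            records.append(
                {
                    "genotype": row["genotype"],
                    "role": row["role"],
                    "location": row["location"],
                    "block": row["block"],
                    "trait": trait,
                    "value": value,
                }
            )
    if unknown:
        raise TrialDataError(
            f"{path}: traits absent from dictionary: {sorted(unknown)}"
        )
    obs = pd.DataFrame.from_records(records, columns=LONG_COLUMNS)
    checks = tuple(sorted(obs.loc[obs["role"] == "check", "genotype"].unique()))
    return TrialDataset(obs, traits, checks)


def read_trial_wide_csv(path: str | Path, dictionary_path: str | Path) -> TrialDataset:
    """Convenience wide-format reader: one column per trait, otherwise the same
    identifier columns as the long format."""
    traits = read_trait_dictionary(dictionary_path)
    wide = pd.read_csv(path, dtype=str, keep_default_na=False)
    id_cols = ["genotype", "role", "location", "block"]
    missing = [c for c in id_cols if c not in wide.columns]
    if missing:
        raise TrialDataError(f"{path}: missing columns {missing}")
    trait_cols = [c for c in wide.columns if c not in id_cols]
    unknown = sorted(set(trait_cols) - set(traits))
    if unknown:
        raise TrialDataError(f"{path}: traits absent from dictionary: {unknown}")
    long = wide.melt(id_vars=id_cols, value_vars=trait_cols, var_name="trait", value_name="value")
    records = []
    for row in long.itertuples(index=False):
        value = _parse_value(row.value, traits[row.trait], str(path))
        records.append(
            {
                "genotype": row.genotype,
                "role": row.role,
                "location": row.location,
                "block": row.block,
                "trait": row.trait,
                "value": value,
            }
        )
    obs = pd.DataFrame.from_records(records, columns=LONG_COLUMNS)
    checks = tuple(sorted(obs.loc[obs["role"] == "check", "genotype"].unique()))
    return TrialDataset(obs, traits, checks)


def write_trial_csv(
    data: TrialDataset, path: str | Path, dictionary_path: str | Path | None = None
) -> None:
    """Write the long-format CSV (RFC 4180, UTF-8); missing values become
    empty fields. Optionally also writes the trait dictionary."""
    out = data.observations.copy()
    out["value"] = out["value"].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else v)
    out.to_csv(path, index=False)
    if dictionary_path is not None:
        write_trait_dictionary(data.traits, dictionary_path)


# -- transforms ----------------------------------------------------------------


def transform_counts(data: TrialDataset, plus_half: bool = False) -> TrialDataset:
    """Return a copy with sqrt-flagged traits replaced by sqrt(x) (or
    sqrt(x + 0.5) when ``plus_half``). Provenance is recorded; re-applying to
    an already transformed trait raises."""
    flagged = [n for n, s in data.traits.items() if s.transform == "sqrt"]
    already = sorted(set(flagged) & set(data.transformed))
    if already:
        raise TrialDataError(f"traits already transformed: {already}")
    if not flagged:
        return data.copy()
    obs = data.observations.copy()
    offset = 0.5 if plus_half else 0.0
    for name in flagged:
        mask = obs["trait"] == name
        vals = pd.to_numeric(obs.loc[mask, "value"])
        negative = vals < 0
        if negative.any():
            bad = obs.loc[mask].loc[negative.fillna(False)]
            first = bad.iloc[0]
            raise TrialDataError(
                f"negative count for trait {name!r} at genotype {first['genotype']!r}, "
                f"location {first['location']!r}, block {first['block']!r}"
            )
        obs.loc[mask, "value"] = np.sqrt(vals + offset)
    return TrialDataset(
        obs, dict(data.traits), tuple(data.checks),
        frozenset(set(data.transformed) | set(flagged)),
    )


# -- validation ----------------------------------------------------------------


def validate_dataset(data: TrialDataset) -> ValidationReport:
    """Report missing values per trait, genotypes absent at some location,
    and blocks missing a check. Purely diagnostic; never raises."""
    report = ValidationReport()
    obs = data.observations

    for name in data.traits:
        sub = obs.loc[obs["trait"] == name, "value"]
        n_missing = int(sub.isna().sum())
        report.missing_value_counts[name] = n_missing
        if n_missing:
            report.issues.append(
                ValidationIssue("warning", "missing-values", f"{name}: {n_missing} missing")
            )

    locations = data.locations
    if len(locations) > 1:
        by_geno = obs.groupby("genotype")["location"].agg(lambda s: frozenset(s))
        all_locs = frozenset(locations)
        for geno in sorted(by_geno.index):
            present = by_geno[geno]
            if present != all_locs:
                absent = sorted(all_locs - present)
                if len(present) == 1:
                    report.single_location_entries.append(geno)
                for loc in absent:
                    report.missing_genotypes.setdefault(loc, []).append(geno)
                report.issues.append(
                    ValidationIssue(
                        "warning",
                        "single-location-entries" if len(present) == 1 else "partial-presence",
                        f"{geno}: absent at {absent}",
                    )
                )

    for loc in locations:
        sub = obs[obs["location"] == loc]
        for block in sorted(sub["block"].unique()):
            present = set(sub.loc[sub["block"] == block, "genotype"])
            for check in data.checks:
                if check not in present:
                    report.blocks_missing_checks.append((loc, block, check))
                    report.issues.append(
                        ValidationIssue(
                            "warning",
                            "check-missing-from-block",
                            f"check {check!r} absent from block {block!r} at {loc!r}",
                        )
                    )

    counts = (
        obs.loc[obs["role"] == "test"]
        .groupby(["genotype", "location", "trait"])
        .size()
    )
    dup = counts[counts > 1]
    for (geno, loc, trait), n in dup.items():
        report.issues.append(
            ValidationIssue(
                "error",
                "replicated-test-entry",
                f"test {geno!r} has {n} plots for {trait!r} at {loc!r}",
            )
        )
    return report
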