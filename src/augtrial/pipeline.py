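"""Orchestration: run the full analysis from one config with a run manifest.

Stages run in dependency order (adjust -> anova -> genetic parameters ->
diversity -> correlation/PCA/clustering -> selection); each stage writes CSV
artifacts into the output directory and the run ends with a ``manifest.json``
recording parameters, seeds, artifact checksums and aggregated warnings.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from augtrial.augmented_design import adjusted_means, anova_single_location, combined_anova
from augtrial.genetic_parameters import estimate_variance_components, genetic_parameter_table
from augtrial.multivariate import (
    cluster_summary,
    correlation_matrix,
    kmeans_clusters,
    pca,
    pca_eigen_frame,
    to_newick,
    upgma_tree,
)
from augtrial.qualitative_diversity import diversity_frame, diversity_table
from augtrial.selection_screening import nutrient_screen, percent_gain_over_best_check
from augtrial.synthetic_data import paper_like_config, simulate_trial
from augtrial.trial_data import read_trial_csv, transform_counts, validate_dataset


class PipelineError(RuntimeError):
    pass


DEFAULT_STAGES = (
    "adjust",
    "anova",
    "genetic_parameters",
    "diversity",
    "correlation",
    "pca",
    "cluster",
    "selection",
)


@dataclass
class RunConfig:
    """Everything needed for one reproducible end-to-end run."""

    out_dir: str = "outputs"
    trial_csv: str | None = None
    traits_csv: str | None = None
    simulate: bool = False
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in DEFAULT_STAGES}
    )
    k: float = 2.056
    min_gain: float = 12.0
    fe_min: float = 60.0
    zn_min: float = 32.0
    kmeans_k: int = 4
    equitability_basis: str = "accessions"
    loading_threshold: float = 0.30
    yield_trait: str = "YLD"
    fe_trait: str = "Fe"
    zn_trait: str = "Zn"
    sqrt_plus_half: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages {sorted(unknown)}")
        for s in DEFAULT_STAGES:
            self.stages.setdefault(s, True)
        if not self.simulate:
            for attr in ("trial_csv", "traits_csv"):
                path = getattr(self, attr)
                if path is None:
                    raise PipelineError("provide trial_csv/traits_csv or set simulate")
                if not Path(path).exists():
                    raise PipelineError(f"{attr} does not exist: {path}")
        if not (self.k > 0 and self.kmeans_k >= 2 and 0 <= self.loading_threshold <= 1):
            raise PipelineError("parameter out of documented range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all enabled stages and return (and write) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    skipped: list[str] = []
    collected_warnings: list[str] = []
    stage_files: list[Path] = []

    def emit(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out_dir / name
        frame.to_csv(path, index=index)
        stage_files.append(path)
        artifacts.append(name)

    def emit_text(text: str, name: str) -> None:
        path = out_dir / name
        path.write_text(text, encoding="utf-8")
        stage_files.append(path)
        artifacts.append(name)

    def run_stage(name: str, fn) -> None:
        if not config.stages.get(name, True):
            skipped.append(name)
            return
        stage_files.clear()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn()
            collected_warnings.extend(f"{name}: {w.message}" for w in caught)
        except Exception as exc:
            for path in stage_files:
                if path.exists():
                    path.rename(path.with_suffix(path.suffix + ".partial"))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # -- input ----------------------------------------------------------------
    if config.simulate:
        data = simulate_trial(paper_like_config(seed=config.seed))
        source = {"simulated": True, "seed": config.seed}
    else:
        data = read_trial_csv(config.trial_csv, config.traits_csv)
        source = {"trial_csv": config.trial_csv, "traits_csv": config.traits_csv}
    report = validate_dataset(data)
    collected_warnings.extend(str(i) for i in report.issues)
    data = transform_counts(data, plus_half=config.sqrt_plus_half)

    quant = data.traits_of_kind("quantitative", "count")
    state: dict = {}

    # -- stages ---------------------------------------------------------------
    def stage_adjust() -> None:
        adj = adjusted_means(data, traits=quant)
        state["adjusted"] = adj
        emit(adj.per_location, "adjusted_means_per_location.csv")
        emit(adj.pooled, "adjusted_means_pooled.csv")

    def stage_anova() -> None:
        adj = state["adjusted"]
        rows = []
        combined_tables = {}
        for trait in quant:
            per_loc = []
            for loc in data.locations:
                table = anova_single_location(data, loc, trait)
                per_loc.append(table)
                frame = table.rows.assign(trait=trait, analysis=f"location:{loc}")
                rows.append(frame)
            comb = combined_anova(adj, per_loc, trait)
            combined_tables[trait] = comb
            rows.append(comb.rows.assign(trait=trait, analysis="combined"))
        state["combined"] = combined_tables
        emit(pd.concat(rows, ignore_index=True), "anova_tables.csv", index=False)

    def stage_genpar() -> None:
        components = [
            estimate_variance_components(tab, n_env=len(data.locations))
            for tab in state["combined"].values()
        ]
        state["components"] = components
        emit(
            genetic_parameter_table(components, k=config.k),
            "genetic_parameters.csv",
            index=False,
        )

    def stage_diversity() -> None:
        if not data.traits_of_kind("qualitative"):
            skipped.append("diversity (no qualitative traits)")
            return
        summaries, mean_h = diversity_table(data, basis=config.equitability_basis)
        frame = diversity_frame(summaries, mean_h)
        emit(frame, "diversity.csv", index=False)
        state["mean_H_prime"] = mean_h

    def stage_correlation() -> None:
        corr = correlation_matrix(state["adjusted"], traits=quant)
        emit(corr.r, "correlations.csv")
        emit(corr.stars(), "correlation_significance.csv")

    def stage_pca() -> None:
        result = pca(state["adjusted"], traits=quant)
        emit(pca_eigen_frame(result), "pca_eigenvalues.csv", index=False)
        emit(result.loadings, "pca_loadings.csv")
        emit(result.scores, "pca_scores.csv")

    def stage_cluster() -> None:
        adj = state["adjusted"]
        order_by = config.yield_trait if config.yield_trait in adj.pooled.columns else None
        km = kmeans_clusters(
            adj, traits=quant, k=config.kmeans_k, seed=config.seed, order_by=order_by
        )
        tree = upgma_tree(adj, traits=quant, k=config.kmeans_k)
        means, counts = cluster_summary(km, adj, traits=quant)
        emit(km.assignments.to_frame(), "cluster_assignments.csv")
        emit(means, "cluster_means.csv")
        emit(counts, "cluster_source_counts.csv")
        emit_text(to_newick(tree), "upgma_dendrogram.nwk")

    def stage_selection() -> None:
        adj = state["adjusted"]
        pooled = adj.pooled
        if config.yield_trait in pooled.columns:
            gains = percent_gain_over_best_check(
                pooled[config.yield_trait].dropna(), list(data.checks)
            )
            emit(gains.ranked, "selection_gains.csv", index=False)
        if config.fe_trait in pooled.columns and config.zn_trait in pooled.columns:
            screen = nutrient_screen(
                pooled[config.fe_trait], pooled[config.zn_trait],
                fe_min=config.fe_min, zn_min=config.zn_min,
            )
            rows = [
                {"screen": name, "genotype": geno}
                for name, members in screen.screens.items()
                for geno in members
            ]
            emit(pd.DataFrame(rows, columns=["screen", "genotype"]), "nutrient_screen.csv", index=False)

    run_stage("adjust", stage_adjust)
    run_stage("anova", stage_anova)
    run_stage("genetic_parameters", stage_genpar)
    run_stage("diversity", stage_diversity)
    run_stage("correlation", stage_correlation)
    run_stage("pca", stage_pca)
    run_stage("cluster", stage_cluster)
    run_stage("selection", stage_selection)

    from importlib.metadata import version as _pkg_version

    try:
        pkg_version = _pkg_version("augtrial")
    except Exception:  # pragma: no cover - editable/unsynced installs
        pkg_version = "unknown"
    manifest = {
        "version": pkg_version,
        "source": source,
        "parameters": {
            "k": config.k, "min_gain": config.min_gain,
            "fe_min": config.fe_min, "zn_min": config.zn_min,
            "kmeans_k": config.kmeans_k, "seed": config.seed,
            "equitability_basis": config.equitability_basis,
            "loading_threshold": config.loading_threshold,
            "sqrt_plus_half": config.sqrt_plus_half,
        },
        "artifacts": sorted(artifacts),
        "checksums": {name: _sha256(out_dir / name) for name in sorted(artifacts)},
        "skipped_stages": skipped,
        "warnings": collected_warnings,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
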