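"""Correlation, PCA and clustering of pooled adjusted genotype means.

All multivariate operations work on a complete-case genotype x trait matrix
(genotypes missing any requested trait are dropped) with per-trait z-score
standardization using the sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from augtrial.augmented_design import AdjustedMeansTable


class MultivariateError(ValueError):
    pass


def _as_matrix(
    adjusted: AdjustedMeansTable | pd.DataFrame, traits: Sequence[str] | None
) -> pd.DataFrame:
    frame = adjusted.pooled if isinstance(adjusted, AdjustedMeansTable) else adjusted
    if traits is not None:
        missing = [t for t in traits if t not in frame.columns]
        if missing:
            raise MultivariateError(f"traits not present: {missing}")
        frame = frame[list(traits)]
    return frame


def _standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """Complete-case z-scores with ddof=1; constant traits dropped with a warning."""
    complete = frame.dropna(axis=0, how="any")
    sd = complete.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(f"constant traits dropped: {constant}", stacklevel=3)
        complete = complete.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (complete - complete.mean()) / sd


# -- correlation ---------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        def star(p: float) -> str:
            if not np.isfinite(p):
                return ""
            if p <= 0.001:
                return "***"
            if p <= 0.01:
                return "**"
            if p <= 0.05:
                return "*"
            return "ns"

        return self.p.map(star)


def correlation_matrix(
    adjusted: AdjustedMeansTable | pd.DataFrame, traits: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with t-based two-sided p-values.

    A constant trait (or a pair with fewer than 3 complete observations)
    yields NaN entries rather than an error.
    """
    frame = _as_matrix(adjusted, traits)
    names = list(frame.columns)
    k = len(names)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        n[i, i] = int(frame[names[i]].notna().sum())
        for j in range(i + 1, k):
            pair = frame[[names[i], names[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                warnings.warn(
                    f"constant trait in pair ({names[i]}, {names[j]}); r undefined",
                    stacklevel=2,
                )
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(names, name="trait")
    return CorrelationMatrix(
        names,
        pd.DataFrame(r, index=idx, columns=names),
        pd.DataFrame(p, index=idx, columns=names),
        pd.DataFrame(n, index=idx, columns=names),
    )


# -- PCA -----------------------------------------------------------------------


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    proportion: np.ndarray  # percent
    cumulative: np.ndarray  # percent
    loadings: pd.DataFrame  # trait x component
    scores: pd.DataFrame  # genotype x component
    retained: int
    important: pd.DataFrame | None = None


def pca(
    adjusted: AdjustedMeansTable | pd.DataFrame, traits: Sequence[str] | None = None
) -> PcaResult:
    """Eigen-decomposition of the correlation matrix of the complete-case
    standardized genotype x trait matrix.

    Components are ordered by descending eigenvalue; each loading vector is
    signed so its largest-magnitude element is positive. ``retained`` counts
    eigenvalues > 1.
    """
    z = _standardize(_as_matrix(adjusted, traits))
    n, k = z.shape
    if n < k + 1:
        raise MultivariateError(f"PCA needs > {k} complete genotypes, got {n}")
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(k):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(eigvecs, index=z.columns, columns=comp_names)
    scores = pd.DataFrame(z.to_numpy() @ eigvecs, index=z.index, columns=comp_names)
    proportion = 100.0 * eigvals / eigvals.sum()
    result = PcaResult(
        eigenvalues=eigvals,
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        loadings=loadings,
        scores=scores,
        retained=int((eigvals > 1.0).sum()),
    )
    result.important = important_loadings(result)
    return result


def important_loadings(result: PcaResult, threshold: float = 0.30) -> pd.DataFrame:
    """Flag loadings with |value| >= threshold (inclusive)."""
    return result.loadings.abs() >= threshold


def pca_eigen_frame(result: PcaResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "component": result.loadings.columns,
            "eigenvalue": result.eigenvalues,
            "proportion_pct": result.proportion,
            "cumulative_pct": result.cumulative,
        }
    )


# -- clustering ----------------------------------------------------------------


@dataclass
class ClusterResult:
    assignments: pd.Series  # genotype -> cluster id (1-based)
    k: int
    method: str
    linkage: np.ndarray | None = None
    labels: list[str] | None = None
    inertia: float | None = None
    metadata: dict = field(default_factory=dict)


def upgma_tree(
    adjusted: AdjustedMeansTable | pd.DataFrame,
    traits: Sequence[str] | None = None,
    k: int | None = None,
    standardize: bool = True,
) -> ClusterResult:
    """Average-linkage (UPGMA) clustering on Euclidean distances of the
    standardized matrix; optionally cut at ``k`` clusters."""
    frame = _as_matrix(adjusted, traits)
    z = _standardize(frame) if standardize else frame.dropna(axis=0, how="any")
    if len(z) < 2:
        raise MultivariateError("UPGMA needs >=2 complete genotypes")
    dist = pdist(z.to_numpy(), metric="euclidean")
    link = hierarchy.linkage(dist, method="average")
    labels = list(z.index)
    if k is not None:
        flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
        assignments = pd.Series(flat, index=z.index, name="cluster")
        k_eff = int(assignments.nunique())
    else:
        assignments = pd.Series(1, index=z.index, name="cluster")
        k_eff = 1
    return ClusterResult(
        assignments=assignments,
        k=k_eff,
        method="upgma_cut" if k is not None else "upgma",
        linkage=link,
        labels=labels,
    )


def to_newick(result: ClusterResult) -> str:
    """Serialize a UPGMA dendrogram as a Newick string with branch lengths
    derived from merge heights."""
    if result.linkage is None or result.labels is None:
        raise MultivariateError("result carries no dendrogram")
    tree = hierarchy.to_tree(result.linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(tree.get_left(), tree.dist)
    right = render(tree.get_right(), tree.dist)
    return f"({left},{right});"


def kmeans_clusters(
    adjusted: AdjustedMeansTable | pd.DataFrame,
    traits: Sequence[str] | None = None,
    k: int = 4,
    seed: int = 0,
    order_by: str | None = None,
    standardize: bool = True,
) -> ClusterResult:
    """K-means (k-means++ init, 10 restarts) on the standardized matrix.

    Cluster ids are relabelled 1..k by descending mean of ``order_by`` (by
    convention the yield trait; defaults to the first trait) so reports are
    stable across seeds.
    """
    if k < 2:
        raise MultivariateError("k must be >= 2")
    frame = _as_matrix(adjusted, traits)
    z = _standardize(frame) if standardize else frame.dropna(axis=0, how="any")
    if k > len(z):
        raise MultivariateError(f"k={k} exceeds {len(z)} complete genotypes")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw_labels = km.fit_predict(z.to_numpy())
    raw = pd.Series(raw_labels, index=z.index)

    order_trait = order_by if order_by in frame.columns else frame.columns[0]
    means = frame.loc[z.index, order_trait].groupby(raw).mean()
    ranked = means.sort_values(ascending=False).index
    relabel = {old: new + 1 for new, old in enumerate(ranked)}
    assignments = raw.map(relabel).rename("cluster")
    return ClusterResult(
        assignments=assignments,
        k=k,
        method="kmeans",
        inertia=float(km.inertia_),
        metadata={"seed": seed, "order_by": order_trait, "n_init": 10},
    )


def cluster_summary(
    result: ClusterResult,
    adjusted: AdjustedMeansTable | pd.DataFrame,
    origins: Mapping[str, str] | None = None,
    traits: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster unweighted trait means and per-origin genotype counts.

    Genotypes without an origin entry are tallied under ``unknown``.
    """
    frame = _as_matrix(adjusted, traits)
    frame = frame.loc[frame.index.intersection(result.assignments.index)]
    grouped = frame.groupby(result.assignments.loc[frame.index])
    cluster_means = grouped.mean()
    cluster_means.index.name = "cluster"

    origins = origins or {}
    origin_series = pd.Series(
        {g: origins.get(g, "unknown") for g in result.assignments.index},
        name="origin",
    )
    source_counts = (
        pd.crosstab(result.assignments, origin_series.loc[result.assignments.index])
        .rename_axis(index="cluster", columns="origin")
    )
    return cluster_means, source_counts
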