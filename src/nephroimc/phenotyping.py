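"""Expression normalization, clustering, annotation, and densities.

The normalization chain follows standard mass-cytometry practice:
``x -> asinh(x / cofactor)`` (cofactor 5) to variance-stabilize the
count-like intensities, a per-marker 99th-percentile cap to tame extreme
outliers, and per-marker min-max scaling to [0, 1]. Clustering is
Phenograph-style: a Euclidean kNN graph on the scaled matrix, edges
re-weighted by shared-neighbor (Jaccard) overlap, and modularity
(Leiden) community detection. Clusters are annotated automatically by
correlating their mean expression with the population templates, so the
whole pipeline runs unattended on synthetic cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import PopulationTemplate

__all__ = [
    "ExpressionMatrix",
    "PopulationAnnotation",
    "transform_expression",
    "correct_batch",
    "cluster_cells",
    "annotate_clusters",
    "densities_per_mm2",
    "cluster_mean_heatmap",
]

UNASSIGNED = "unassigned"


@dataclass
class ExpressionMatrix:
    """Cells x markers expression values with their transform state."""

    values: np.ndarray
    markers: list[str]
    transform_state: str = "raw"  # raw | arcsinh | capped | scaled
    cofactor: float = 5.0
    cap_percentile: float = 99.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        if self.values.shape[1] != len(self.markers):
            raise ValueError("marker list length must match the column count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class PopulationAnnotation:
    """Cluster id -> population label with the correlation that chose it."""

    mapping: dict[int, str]
    scores: dict[int, float] = field(default_factory=dict)

    def populations(self) -> list[str]:
        """Distinct non-unassigned labels, in first-appearance order."""
        seen = []
        for v in self.mapping.values():
            if v != UNASSIGNED and v not in seen:
                seen.append(v)
        return seen

    def relabel(self, cluster_labels: np.ndarray) -> np.ndarray:
        return np.array([self.mapping[int(c)] for c in cluster_labels], dtype=object)


def transform_expression(
    table: pd.DataFrame,
    markers: list[str],
    cofactor: float = 5.0,
    cap_percentile: float = 99.0,
) -> ExpressionMatrix:
    """arcsinh -> percentile cap -> min-max scale, per marker.

    The cap percentile is computed across the whole cohort (all cells in
    ``table``), not per ROI. Constant markers scale to all zeros. An
    empty table yields an empty matrix.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if not 0 < cap_percentile <= 100:
        raise ValueError("cap_percentile must be in (0, 100]")
    X = table[markers].to_numpy(dtype=float)
    if X.size == 0:
        return ExpressionMatrix(X.reshape(0, len(markers)), list(markers), "scaled", cofactor, cap_percentile)
    X = np.arcsinh(X / cofactor)
    caps = np.percentile(X, cap_percentile, axis=0)
    X = np.minimum(X, caps[None, :])
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    X = (X - lo) / safe
    X[:, rng == 0] = 0.0
    return ExpressionMatrix(X, list(markers), "scaled", cofactor, cap_percentile)


def correct_batch(
    expr: ExpressionMatrix, batches: np.ndarray | pd.Series, mode: str = "median"
) -> ExpressionMatrix:
    """Shift-only batch alignment.

    Per batch and marker, subtract the batch median and add the global
    median; ranks within a batch are untouched. ``mode="none"`` is the
    identity pass-through for externally corrected matrices.
    """
    batches = np.asarray(batches)
    if len(batches) != expr.n_cells:
        raise ValueError("one batch label per cell required")
    if mode == "none":
        return expr
    if mode != "median":
        raise ValueError(f"unknown batch-correction mode {mode!r}")
    uniq = np.unique(batches)
    X = expr.values.copy()
    if len(uniq) <= 1 or X.size == 0:
        return ExpressionMatrix(X, expr.markers, expr.transform_state, expr.cofactor, expr.cap_percentile)
    global_med = np.median(X, axis=0)
    for b in uniq:
        sel = batches == b
        X[sel] += global_med - np.median(X[sel], axis=0)
    return ExpressionMatrix(X, expr.markers, expr.transform_state, expr.cofactor, expr.cap_percentile)


def cluster_cells(
    expr: ExpressionMatrix,
    k_graph: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Phenograph-style kNN-graph community detection.

    Builds the Euclidean kNN graph on the scaled matrix, weights each
    edge by the Jaccard overlap of the two cells' neighbor sets, and
    maximizes modularity with the Leiden algorithm (RBConfiguration at
    the given resolution). Deterministic for a fixed seed.
    """
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = expr.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if k_graph < 1:
        raise ValueError("k_graph must be >= 1")
    if k_graph >= n:
        warnings.warn(f"k_graph={k_graph} >= n={n}; lowering to {n - 1}")
        k_graph = n - 1

    nn = NearestNeighbors(n_neighbors=k_graph + 1).fit(expr.values)
    _, idx = nn.kneighbors(expr.values)
    idx = idx[:, 1:]  # drop self

    neighbor_sets = [set(row) for row in idx]
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        si = neighbor_sets[i]
        for j in idx[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in edges:
                continue
            sj = neighbor_sets[int(j)]
            inter = len(si & sj)
            union = len(si | sj)
            w = inter / union if union else 0.0
            edges[(a, b)] = max(w, 1e-9)

    g = ig.Graph(n=n, edges=list(edges.keys()))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(edges.values()),
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def annotate_clusters(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    templates: list[PopulationTemplate],
    min_score: float = 0.3,
) -> PopulationAnnotation:
    """Assign each cluster the best-correlated population template.

    Cluster-mean expression and template signatures are z-scored across
    markers before Pearson correlation; a cluster whose best score falls
    below ``min_score`` is labelled unassigned. Several clusters may map
    to the same population (over-segmented clusters merge downstream).
    """
    labels = np.asarray(labels)
    if len(labels) != expr.n_cells:
        raise ValueError("one cluster label per cell required")
    # templates are defined on the raw scale; apply the same monotone
    # transform chain so shapes are comparable
    tmpl = np.array([np.arcsinh(t.signature / expr.cofactor) for t in templates])
    tz = np.array([_zscore(row) for row in tmpl])
    mapping: dict[int, str] = {}
    scores: dict[int, float] = {}
    for c in np.unique(labels):
        mean = expr.values[labels == c].mean(axis=0)
        mz = _zscore(mean)
        if not mz.any():
            mapping[int(c)], scores[int(c)] = UNASSIGNED, 0.0
            continue
        r = tz @ mz / len(mz)  # Pearson r of z-scored vectors
        best = int(np.argmax(r))
        score = float(r[best])
        mapping[int(c)] = templates[best].name if score >= min_score else UNASSIGNED
        scores[int(c)] = score
    return PopulationAnnotation(mapping, scores)


def densities_per_mm2(
    table: pd.DataFrame,
    roi_area_mm2: float | dict[str, float],
    populations: list[str] | None = None,
    population_col: str = "population",
) -> pd.DataFrame:
    """Per-(sample, ROI, population) counts and densities in cells/mm^2.

    ``roi_area_mm2`` is a scalar (all ROIs equal) or a mapping roi_id ->
    area. Population densities within an ROI sum to the total density by
    construction. ROIs present in the table but empty of a population
    report density 0 for it.
    """
    if populations is None:
        populations = sorted(table[population_col].dropna().unique())
    counts = (
        table.groupby(["sample_id", "roi_id", population_col], observed=True)
        .size()
        .unstack(population_col, fill_value=0)
        .reindex(columns=populations, fill_value=0)
    )
    counts = counts.reset_index()
    if isinstance(roi_area_mm2, dict):
        areas = counts["roi_id"].map(roi_area_mm2)
        if areas.isna().any():
            raise ValueError("missing ROI area for some roi_id")
    else:
        areas = pd.Series(float(roi_area_mm2), index=counts.index)
    if (areas <= 0).any():
        raise ValueError("ROI area must be positive")
    long = counts.melt(
        id_vars=["sample_id", "roi_id"], var_name="population", value_name="count"
    )
    long["roi_area_mm2"] = long["roi_id"].map(dict(zip(counts["roi_id"], areas)))
    long["density_per_mm2"] = long["count"] / long["roi_area_mm2"]
    return long


def cluster_mean_heatmap(expr: ExpressionMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Cluster x marker mean-expression matrix, z-scored per marker."""
    labels = np.asarray(labels)
    rows = {}
    for c in np.unique(labels):
        rows[c] = expr.values[labels == c].mean(axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=expr.markers)
    sd = df.std(axis=0, ddof=0).replace(0, 1.0)
    return (df - df.mean(axis=0)) / sd
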