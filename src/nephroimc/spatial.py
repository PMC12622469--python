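"""Cellular-neighborhood and spatial-interaction statistics.

Three complementary views of tissue organization, all computed on
annotated cell centroids in micrometres, always within a single ROI
(neighbor relations never cross ROI boundaries):

* **Cellular neighborhoods (CN)** — each cell is summarized by the
  population composition of its k = 10 nearest neighbors; profiles are
  pooled over the cohort and k-means clustered (k = 15) into recurrent
  neighborhood classes, named after their three most enriched
  populations. Voronoi maps visually validate the classes on the tissue.
* **Pairwise interaction tests** — for an ordered pair (A, B), the
  statistic is the mean number of B cells among the k nearest neighbors
  of A cells; the null distribution shuffles population labels over the
  fixed cell positions of the ROI, so the test asks whether the *label
  arrangement* is non-random given the point pattern. Attraction gives
  z > 0, repulsion z < 0; p-values are empirical and Benjamini-Hochberg
  adjusted across pairs.
* **Patch analysis** — mean counts of B cells in fixed annuli
  (0-10, 10-20, 20-30 um) around A cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NeighborhoodProfiles",
    "CNAssignment",
    "knn_profiles",
    "cluster_neighborhoods",
    "voronoi_map",
    "interaction_permutation_test",
    "aggregate_interactions",
    "patch_distance_analysis",
    "DEFAULT_BINS",
]

DEFAULT_K = 10
DEFAULT_K_CN = 15
DEFAULT_BINS = [(0.0, 10.0), (10.0, 20.0), (20.0, 30.0)]


@dataclass
class NeighborhoodProfiles:
    """Per-cell kNN composition vectors over a fixed population order."""

    composition: np.ndarray  # (n_cells, n_populations), rows sum to 1 (or 0)
    populations: list[str]
    cell_index: pd.DataFrame  # sample_id, roi_id, cell_id, k_used
    k: int = DEFAULT_K


@dataclass
class CNAssignment:
    """k-means neighborhood classes over pooled composition profiles."""

    labels: np.ndarray  # CN class per cell, values in {1..K}
    centroids: np.ndarray  # (K, n_populations)
    populations: list[str]
    cn_names: dict[int, str] = field(default_factory=dict)
    empty_classes: list[int] = field(default_factory=list)


def _knn_indices(xy: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Indices of the k nearest neighbors (self excluded) per point.

    Input must be ordered by cell_id so distance ties resolve toward the
    lower cell_id. Returns (indices array (n, k_used), k_used).
    """
    n = len(xy)
    k_used = min(k, n - 1)
    if k_used < 1:
        return np.zeros((n, 0), dtype=int), 0
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k_used + 1)
    idx = np.atleast_2d(idx)
    # drop self (distance 0 comes first; at exact-duplicate positions the
    # self index may appear later in the row)
    out = np.empty((n, k_used), dtype=int)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k_used]
        if len(row) < k_used:  # duplicate-position edge case
            row = np.concatenate([row, idx[i][idx[i] != i][: k_used - len(row)]])
        out[i] = row
    return out, k_used


def knn_profiles(
    cells: pd.DataFrame,
    k: int = DEFAULT_K,
    populations: list[str] | None = None,
    population_col: str = "population",
) -> NeighborhoodProfiles:
    """kNN composition profile for every cell, computed within each ROI.

    ``cells`` needs columns sample_id, roi_id, cell_id, x_um, y_um and
    the population column. ROIs with fewer cells than ``k + 1`` use all
    available neighbors and record the reduced ``k_used``; a single-cell
    ROI yields an all-zero profile (flagged by ``k_used = 0``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if populations is None:
        populations = sorted(cells[population_col].dropna().unique())
    pop_index = {p: i for i, p in enumerate(populations)}
    P = len(populations)

    comp_parts, index_parts = [], []
    for roi_id, sub in cells.groupby("roi_id", sort=True, observed=True):
        sub = sub.sort_values("cell_id", kind="mergesort")
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        labels = np.array([pop_index.get(p, -1) for p in sub[population_col]])
        idx, k_used = _knn_indices(xy, k)
        comp = np.zeros((len(sub), P))
        if k_used >= 1:
            neigh = labels[idx]  # (n, k_used)
            for j in range(P):
                comp[:, j] = (neigh == j).sum(axis=1)
            comp /= k_used
        comp_parts.append(comp)
        index_parts.append(
            pd.DataFrame(
                {
                    "sample_id": sub["sample_id"].to_numpy(),
                    "roi_id": roi_id,
                    "cell_id": sub["cell_id"].to_numpy(),
                    "k_used": k_used,
                }
            )
        )
    composition = np.vstack(comp_parts) if comp_parts else np.zeros((0, P))
    cell_index = pd.concat(index_parts, ignore_index=True) if index_parts else pd.DataFrame(
        columns=["sample_id", "roi_id", "cell_id", "k_used"]
    )
    return NeighborhoodProfiles(composition, list(populations), cell_index, k)


def cluster_neighborhoods(
    profiles: NeighborhoodProfiles, K: int = DEFAULT_K_CN, seed: int = 0
) -> CNAssignment:
    """k-means the pooled composition profiles into K neighborhood classes.

    Uses k-means++ initialization with 10 restarts at a fixed seed. A CN
    class is named after the three populations most over-represented in
    its centroid relative to the cohort-average composition. Classes are
    numbered 1..K; empty classes (possible after reassignment) are
    reported, not dropped.
    """
    from sklearn.cluster import KMeans

    n = len(profiles.composition)
    if K < 1:
        raise ValueError("K must be >= 1")
    if n == 0:
        raise ValueError("no profiles to cluster")
    if n < K:
        warnings.warn(f"only {n} profiles for K={K}; lowering K to {n}")
        K = n
    km = KMeans(n_clusters=K, n_init=10, random_state=int(seed))
    labels = km.fit_predict(profiles.composition) + 1  # 1-based classes
    centroids = km.cluster_centers_

    cohort_mean = profiles.composition.mean(axis=0)
    safe = np.where(cohort_mean > 0, cohort_mean, np.inf)
    names = {}
    for c in range(K):
        enrich = centroids[c] / safe
        top = np.argsort(enrich)[::-1][:3]
        names[c + 1] = "+".join(profiles.populations[t] for t in top)
    empty = [c + 1 for c in range(K) if (labels == c + 1).sum() == 0]
    if empty:
        warnings.warn(f"empty CN classes: {empty}")
    return CNAssignment(labels, centroids, list(profiles.populations), names, empty)


def voronoi_map(
    cells: pd.DataFrame, roi_size_um: tuple[float, float]
) -> dict[int, "object"]:
    """Voronoi tessellation of an ROI, clipped to its rectangle.

    Returns a mapping cell_id -> shapely Polygon; polygons partition the
    rectangle. Requires at least 3 non-collinear cells.
    """
    from shapely.geometry import MultiPoint, Point, box
    from shapely.ops import voronoi_diagram

    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) < 3:
        raise ValueError(f"Voronoi needs >= 3 cells, got {len(xy)}")
    # collinearity: rank of centered coordinates
    centered = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("cells are collinear; Voronoi tessellation undefined")
    roi = box(0.0, 0.0, float(roi_size_um[0]), float(roi_size_um[1]))
    diagram = voronoi_diagram(MultiPoint([Point(p) for p in xy]), envelope=roi)
    ids = cells["cell_id"].to_numpy()
    out: dict[int, object] = {}
    polys = list(diagram.geoms)
    for i, p in enumerate(xy):
        pt = Point(p)
        owner = None
        for poly in polys:
            if poly.covers(pt):
                owner = poly
                break
        if owner is None:  # point on a shared edge after clipping
            owner = min(polys, key=lambda g: g.distance(pt))
        out[int(ids[i])] = owner.intersection(roi)
    return out


def voronoi_to_geojson(polygons: dict[int, "object"]) -> dict:
    """GeoJSON-style FeatureCollection of Voronoi polygons keyed by cell."""
    feats = []
    for cid, poly in polygons.items():
        feats.append(
            {
                "type": "Feature",
                "properties": {"cell_id": cid},
                "geometry": poly.__geo_interface__,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def interaction_permutation_test(
    cells: pd.DataFrame,
    k: int = DEFAULT_K,
    n_perm: int = 1000,
    seed: int = 0,
    populations: list[str] | None = None,
    population_col: str = "population",
) -> pd.DataFrame:
    """Label-permutation test for spatial attraction/repulsion, per ROI.

    For each ROI and ordered population pair (A, B): the observed
    statistic is the mean count of B cells among the k nearest neighbors
    of A cells; ``n_perm`` label shuffles over the fixed positions give
    the null. Two-sided empirical p = (1 + #{|perm - mean| >= |obs -
    mean|}) / (n_perm + 1), so p is never 0 and never below
    1/(n_perm+1).

    Returns a tidy frame with one row per (roi_id, type_a, type_b):
    columns n_a, observed, null_mean, null_sd, z, p. Pairs with no A
    cell in an ROI are reported with NaN statistics (absent, not zero).
    Requires at least two populations present per ROI; single-population
    ROIs are skipped with a warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if populations is None:
        populations = sorted(cells[population_col].dropna().unique())
    pop_index = {p: i for i, p in enumerate(populations)}
    P = len(populations)
    rng = np.random.default_rng(seed)

    rows = []
    for roi_id, sub in cells.groupby("roi_id", sort=True, observed=True):
        sub = sub.sort_values("cell_id", kind="mergesort")
        labels = np.array([pop_index.get(p, -1) for p in sub[population_col]])
        present = np.unique(labels[labels >= 0])
        if len(present) < 2:
            warnings.warn(f"ROI {roi_id!r} has fewer than 2 populations; skipped")
            continue
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        idx, k_used = _knn_indices(xy, k)
        if k_used < 1:
            continue
        n = len(labels)

        def pair_stats(lab: np.ndarray) -> np.ndarray:
            """(P, P) matrix: mean B-neighbor count per A cell; NaN if no A."""
            neigh = lab[idx]  # (n, k_used)
            nb = np.zeros((n, P))
            for j in range(P):
                nb[:, j] = (neigh == j).sum(axis=1)
            stats = np.full((P, P), np.nan)
            for a in range(P):
                sel = lab == a
                if sel.any():
                    stats[a] = nb[sel].mean(axis=0)
            return stats

        obs = pair_stats(labels)

        # vectorized permutations
        perm_labels = np.tile(labels, (n_perm, 1))
        perm_labels = rng.permuted(perm_labels, axis=1)
        neigh = perm_labels[:, idx]  # (n_perm, n, k_used)
        nb = np.zeros((n_perm, n, P), dtype=np.float32)
        for j in range(P):
            nb[:, :, j] = (neigh == j).sum(axis=2)
        onehot = np.zeros((n_perm, n, P), dtype=np.float32)
        for j in range(P):
            onehot[:, :, j] = perm_labels == j
        counts = onehot.sum(axis=1)  # (n_perm, P)
        sums = np.einsum("pna,pnb->pab", onehot, nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_stats = sums / counts[:, :, None]  # (n_perm, P, P)

        with warnings.catch_warnings():
            # populations absent from the ROI give all-NaN permutation slices
            warnings.simplefilter("ignore", category=RuntimeWarning)
            null_mean = np.nanmean(perm_stats, axis=0)
            null_sd = np.nanstd(perm_stats, axis=0)
        n_a = np.array([(labels == a).sum() for a in range(P)])
        for a in range(P):
            for b in range(P):
                if n_a[a] == 0:
                    rows.append(
                        dict(roi_id=roi_id, type_a=populations[a], type_b=populations[b],
                             n_a=0, observed=np.nan, null_mean=np.nan, null_sd=np.nan,
                             z=np.nan, p=np.nan)
                    )
                    continue
                o = obs[a, b]
                dist = perm_stats[:, a, b]
                dist = dist[~np.isnan(dist)]
                mu = dist.mean() if len(dist) else np.nan
                sd = dist.std() if len(dist) else np.nan
                extreme = int(np.sum(np.abs(dist - mu) >= np.abs(o - mu) - 1e-12))
                p = (1 + extreme) / (len(dist) + 1)
                z = (o - mu) / sd if sd and sd > 0 else 0.0
                rows.append(
                    dict(roi_id=roi_id, type_a=populations[a], type_b=populations[b],
                         n_a=int(n_a[a]), observed=o, null_mean=mu, null_sd=sd, z=z, p=p)
                )
    return pd.DataFrame(rows)


def aggregate_interactions(per_roi: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level interaction summary across ROIs.

    Per ordered pair, averages the per-ROI observed statistic, null mean
    and z weighted by the number of A cells, combines the per-ROI
    empirical p-values by the weighted Stouffer method, and applies
    Benjamini-Hochberg across pairs (column ``q``).
    """
    from scipy.stats import norm

    rows = []
    for (a, b), sub in per_roi.groupby(["type_a", "type_b"], sort=True, observed=True):
        sub = sub.dropna(subset=["observed"])
        if sub.empty:
            continue
        w = sub["n_a"].to_numpy(dtype=float)
        zsigned = norm.isf(np.clip(sub["p"].to_numpy() / 2.0, 1e-15, 1 - 1e-15)) * np.sign(
            sub["z"].to_numpy()
        )
        z_comb = float(np.sum(w * zsigned) / np.sqrt(np.sum(w**2)))
        p_comb = float(2 * norm.sf(abs(z_comb)))
        rows.append(
            dict(
                type_a=a,
                type_b=b,
                n_rois=len(sub),
                n_a_total=int(w.sum()),
                observed=float(np.average(sub["observed"], weights=w)),
                null_mean=float(np.average(sub["null_mean"], weights=w)),
                z=float(np.average(sub["z"], weights=w)),
                p=max(p_comb, np.finfo(float).tiny),
            )
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def patch_distance_analysis(
    cells: pd.DataFrame,
    bins: list[tuple[float, float]] | None = None,
    populations: list[str] | None = None,
    population_col: str = "population",
) -> pd.DataFrame:
    """Mean count of B cells in distance annuli around A cells.

    Bins are half-open [lo, hi) in um (defaults 0-10, 10-20, 20-30).
    Computed per ROI (self excluded) and averaged across ROIs weighted
    by A-cell counts. Returns columns type_a, type_b, bin_lo, bin_hi,
    mean_count.
    """
    bins = bins if bins is not None else DEFAULT_BINS
    if populations is None:
        populations = sorted(cells[population_col].dropna().unique())
    pop_index = {p: i for i, p in enumerate(populations)}
    P = len(populations)
    B = len(bins)
    max_r = max(hi for _, hi in bins)

    sums = np.zeros((P, P, B))
    weights = np.zeros(P)
    for _, sub in cells.groupby("roi_id", sort=True, observed=True):
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        labels = np.array([pop_index.get(p, -1) for p in sub[population_col]])
        n = len(xy)
        if n == 0:
            continue
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=max_r * (1 + 1e-12), output_type="ndarray")
        # counts[i, b_label, bin]
        counts = np.zeros((n, P, B))
        if len(pairs):
            d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
            for bi, (lo, hi) in enumerate(bins):
                inbin = (d >= lo) & (d < hi)
                for i, j in pairs[inbin]:
                    if labels[j] >= 0:
                        counts[i, labels[j], bi] += 1
                    if labels[i] >= 0:
                        counts[j, labels[i], bi] += 1
        for a in range(P):
            sel = labels == a
            na = int(sel.sum())
            if na == 0:
                continue
            sums[a] += counts[sel].sum(axis=0)
            weights[a] += na
    rows = []
    for a in range(P):
        for b in range(P):
            for bi, (lo, hi) in enumerate(bins):
                mean = sums[a, b, bi] / weights[a] if weights[a] > 0 else np.nan
                rows.append(
                    dict(type_a=populations[a], type_b=populations[b],
                         bin_lo=lo, bin_hi=hi, mean_count=mean)
                )
    return pd.DataFrame(rows)
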