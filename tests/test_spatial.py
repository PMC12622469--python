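"""Neighborhood profiles, CN clustering, Voronoi, interactions, patches."""

import numpy as np
import pandas as pd
import pytest

from nephroimc.spatial import (
    aggregate_interactions,
    cluster_neighborhoods,
    interaction_permutation_test,
    knn_profiles,
    patch_distance_analysis,
    voronoi_map,
)


def point_table(xy, pops, roi_id="r1", sample_id="s1"):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "roi_id": roi_id,
            "cell_id": np.arange(len(xy)),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "population": pops,
        }
    )


class TestKnnProfiles:
    def test_homogeneous_roi_pure_composition(self):
        rng = np.random.default_rng(0)
        cells = point_table(rng.uniform(0, 100, (30, 2)), ["A"] * 30)
        prof = knn_profiles(cells, k=10, populations=["A", "B"])
        np.testing.assert_allclose(prof.composition[:, 0], 1.0)
        np.testing.assert_allclose(prof.composition[:, 1], 0.0)

    def test_line_example_hand_computed(self):
        # cells at x = 0, 1, 2, 10 with types A, A, B, B; k=2:
        # neighbors of the cell at 0 are those at 1 (A) and 2 (B)
        cells = point_table([[0, 0], [1, 0], [2, 0], [10, 0]], ["A", "A", "B", "B"])
        prof = knn_profiles(cells, k=2, populations=["A", "B"])
        np.testing.assert_allclose(prof.composition[0], [0.5, 0.5])

    def test_small_roi_reduces_k(self):
        rng = np.random.default_rng(1)
        cells = point_table(rng.uniform(0, 50, (5, 2)), ["A"] * 5)
        prof = knn_profiles(cells, k=10, populations=["A"])
        assert (prof.cell_index["k_used"] == 4).all()

    def test_compositions_sum_to_one(self, annotated_cells):
        prof = knn_profiles(annotated_cells, k=10)
        sums = prof.composition.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_single_cell_roi_zero_profile(self):
        cells = point_table([[5, 5]], ["A"])
        prof = knn_profiles(cells, k=10, populations=["A"])
        assert prof.composition.sum() == 0.0
        assert prof.cell_index["k_used"].iloc[0] == 0


class TestClusterNeighborhoods:
    def test_planted_motifs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        # neighborhoods: pure-A vs A/B-mixed
        pure = np.tile([1.0, 0.0], (60, 1))
        mixed = np.tile([0.5, 0.5], (60, 1))
        from nephroimc.spatial import NeighborhoodProfiles

        prof = NeighborhoodProfiles(
            np.vstack([pure, mixed]), ["A", "B"],
            pd.DataFrame({"sample_id": "s", "roi_id": "r",
                          "cell_id": np.arange(120), "k_used": 10}),
        )
        cn = cluster_neighborhoods(prof, K=2, seed=0)
        truth = np.repeat([0, 1], 60)
        assert adjusted_rand_score(truth, cn.labels) == 1.0

    def test_default_run_defines_15_classes(self, annotated_cells):
        prof = knn_profiles(annotated_cells, k=10)
        cn = cluster_neighborhoods(prof, K=15, seed=0)
        assert cn.centroids.shape[0] == 15
        assert set(np.unique(cn.labels)) <= set(range(1, 16))
        assert all(len(name.split("+")) == 3 for name in cn.cn_names.values())

    def test_identical_profiles_single_class(self):
        from nephroimc.spatial import NeighborhoodProfiles

        prof = NeighborhoodProfiles(
            np.tile([0.5, 0.5], (40, 1)), ["A", "B"],
            pd.DataFrame({"sample_id": "s", "roi_id": "r",
                          "cell_id": np.arange(40), "k_used": 10}),
        )
        with pytest.warns(UserWarning, match="empty CN"):
            cn = cluster_neighborhoods(prof, K=3, seed=0)
        assert len(np.unique(cn.labels)) == 1

    def test_invariance_to_ordering_and_translation(self, annotated_cells):
        from sklearn.metrics import adjusted_rand_score

        sub = annotated_cells[annotated_cells["roi_id"].isin(
            annotated_cells["roi_id"].unique()[:4])].reset_index(drop=True)
        prof1 = knn_profiles(sub, k=10)
        cn1 = cluster_neighborhoods(prof1, K=5, seed=0)
        shuffled = sub.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shifted = shuffled.assign(x_um=shuffled["x_um"] + 1000.0,
                                  y_um=shuffled["y_um"] - 500.0)
        prof2 = knn_profiles(shifted, k=10)
        cn2 = cluster_neighborhoods(prof2, K=5, seed=0)
        key1 = prof1.cell_index[["roi_id", "cell_id"]].apply(tuple, axis=1)
        key2 = prof2.cell_index[["roi_id", "cell_id"]].apply(tuple, axis=1)
        l2 = pd.Series(cn2.labels, index=key2).reindex(key1).to_numpy()
        assert adjusted_rand_score(cn1.labels, l2) == 1.0


class TestVoronoi:
    def test_2x2_grid_quadrants(self):
        cells = point_table([[25, 25], [75, 25], [25, 75], [75, 75]], ["A"] * 4)
        polys = voronoi_map(cells, (100.0, 100.0))
        areas = sorted(p.area for p in polys.values())
        np.testing.assert_allclose(areas, [2500.0] * 4)

    def test_partition_of_roi(self):
        rng = np.random.default_rng(2)
        cells = point_table(rng.uniform(0, 200, (40, 2)), ["A"] * 40)
        polys = voronoi_map(cells, (200.0, 200.0))
        total = sum(p.area for p in polys.values())
        assert total == pytest.approx(200.0 * 200.0, rel=1e-6)

    def test_each_cell_inside_own_polygon(self):
        from shapely.geometry import Point

        rng = np.random.default_rng(3)
        cells = point_table(rng.uniform(0, 100, (25, 2)), ["A"] * 25)
        polys = voronoi_map(cells, (100.0, 100.0))
        for _, row in cells.iterrows():
            assert polys[int(row["cell_id"])].covers(Point(row["x_um"], row["y_um"]))

    def test_too_few_or_collinear_fails(self):
        with pytest.raises(ValueError, match=">= 3"):
            voronoi_map(point_table([[1, 1], [2, 2]], ["A", "A"]), (10.0, 10.0))
        with pytest.raises(ValueError, match="collinear"):
            voronoi_map(point_table([[1, 1], [2, 2], [3, 3]], ["A"] * 3), (10.0, 10.0))


class TestInteractions:
    def csr_cells(self, n_rois=200, n=80, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for r in range(n_rois):
            xy = rng.uniform(0, 300, (n, 2))
            pops = rng.choice(["A", "B"], size=n)
            frames.append(point_table(xy, pops, roi_id=f"r{r:03d}"))
        return pd.concat(frames, ignore_index=True)

    def test_type_i_error_calibrated_under_csr(self):
        cells = self.csr_cells()
        res = interaction_permutation_test(cells, k=10, n_perm=199, seed=1)
        for (_, _), sub in res.groupby(["type_a", "type_b"]):
            frac = (sub["p"] < 0.05).mean()
            assert 0.02 <= frac <= 0.09

    def test_p_never_zero_and_reproducible(self):
        cells = self.csr_cells(n_rois=3, seed=5)
        r1 = interaction_permutation_test(cells, k=10, n_perm=99, seed=2)
        r2 = interaction_permutation_test(cells, k=10, n_perm=99, seed=2)
        pd.testing.assert_frame_equal(r1, r2)
        assert (r1["p"] > 0).all()
        assert (r1["p"] >= 1.0 / 100.0).all()

    def test_planted_attraction_detected_across_seeds(self):
        # Thomas-coupled A-B should read as attraction (z>0, q<0.05)
        from nephroimc.panel import default_panel
        from nephroimc.preprocess import SpilloverMatrix
        from nephroimc.synthetic import (
            CohortSpec,
            PopulationTemplate,
            SpatialRule,
            default_templates,
            simulate_points,
        )

        # the two coupled types plus an unclustered epithelial background:
        # the label-shuffle null preserves the point pattern, so A-B
        # co-clustering is only detectable relative to other labels
        tmpl = [t for t in default_templates() if t.name in ("cd8_t", "fibroblast", "epithelial")]
        tmpl = [
            PopulationTemplate(
                t.name, t.signature,
                {"control": 600.0 if t.name == "epithelial" else 200.0,
                 "case": 600.0 if t.name == "epithelial" else 200.0},
                t.nucleus_radius_px,
            )
            for t in tmpl
        ]
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            spec = CohortSpec(
                n_control_samples=1, n_case_samples=1, rois_per_control=2, rois_per_case=2,
                roi_size_um=(400.0, 400.0), templates=tmpl,
                rules=[SpatialRule("cd8_t", "fibroblast", "attraction", strength=8.0, radius_um=15.0)],
                spillover=SpilloverMatrix.identity(default_panel().markers),
                noise_cv=0.0, shot_noise=False, seed=s,
            )
            frames = []
            for k in range(spec.n_rois):
                pts, types, _ = simulate_points(spec, k)
                frames.append(point_table(pts, types, roi_id=f"r{k}"))
            cells = pd.concat(frames, ignore_index=True)
            res = interaction_permutation_test(cells, k=10, n_perm=199, seed=s)
            agg = aggregate_interactions(res)
            row = agg[(agg["type_a"] == "cd8_t") & (agg["type_b"] == "fibroblast")].iloc[0]
            if row["z"] > 0 and row["q"] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_single_population_flagged_not_fabricated(self):
        cells = point_table(np.random.default_rng(0).uniform(0, 100, (20, 2)), ["A"] * 20)
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = interaction_permutation_test(cells, k=5, n_perm=99, populations=["A", "B"])
        assert res.empty

    def test_absent_pair_reported_as_nan(self):
        rng = np.random.default_rng(1)
        cells = point_table(rng.uniform(0, 100, (30, 2)), ["A"] * 15 + ["B"] * 15)
        res = interaction_permutation_test(cells, k=5, n_perm=99, seed=0,
                                           populations=["A", "B", "C"])
        absent = res[res["type_a"] == "C"]
        assert absent["observed"].isna().all()
        assert (absent["n_a"] == 0).all()


class TestPatch:
    def test_hand_computed_bins(self):
        cells = point_table([[0, 0], [15, 0]], ["A", "B"])
        out = patch_distance_analysis(cells, populations=["A", "B"])
        ab = out[(out["type_a"] == "A") & (out["type_b"] == "B")]
        np.testing.assert_allclose(ab.sort_values("bin_lo")["mean_count"], [0, 1, 0])

    def test_boundary_half_open(self):
        cells = point_table([[0, 0], [10, 0]], ["A", "B"])
        out = patch_distance_analysis(cells, populations=["A", "B"])
        ab = out[(out["type_a"] == "A") & (out["type_b"] == "B")].sort_values("bin_lo")
        np.testing.assert_allclose(ab["mean_count"], [0, 1, 0])  # 10 um -> [10, 20)

    def test_no_b_cells_zero_counts(self):
        cells = point_table([[0, 0], [5, 5]], ["A", "A"])
        out = patch_distance_analysis(cells, populations=["A", "B"])
        ab = out[(out["type_a"] == "A") & (out["type_b"] == "B")]
        assert (ab["mean_count"] == 0).all()


class TestCohortDirectionality:
    def test_trio_cn_more_abundant_in_case_group(self):
        """The CN class most enriched in the macrophage/CD8/fibroblast trio
        should occupy a larger cell fraction in case ROIs than control."""
        from scipy.stats import mannwhitneyu

        from nephroimc.synthetic import desk_spec, generate_cohort

        wins = 0
        n_seeds = 4
        trio = {"resident_macrophage", "cd8_t", "fibroblast"}
        for s in range(n_seeds):
            _, truth = generate_cohort(desk_spec(seed=100 + s), with_expression=False)
            cells = truth.cells.rename(columns={"type": "population"})
            prof = knn_profiles(cells, k=10)
            cn = cluster_neighborhoods(prof, K=15, seed=s)
            enrich = np.array([
                cn.centroids[c, [cn.populations.index(p) for p in trio]].sum()
                for c in range(cn.centroids.shape[0])
            ])
            target = int(np.argmax(enrich)) + 1
            assign = prof.cell_index.copy()
            assign["is_target"] = cn.labels == target
            frac = assign.groupby("roi_id")["is_target"].mean()
            groups = cells.drop_duplicates("roi_id").set_index("roi_id")["group"]
            case = frac[groups == "case"]
            ctrl = frac[groups == "control"]
            p = mannwhitneyu(case, ctrl, alternative="greater").pvalue
            if p < 0.05:
                wins += 1
        assert wins >= n_seeds / 2
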