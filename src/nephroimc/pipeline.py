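"""End-to-end orchestrator: simulate -> preprocess -> segment ->
phenotype -> spatial -> stats.

Each stage writes its artifacts under a named subdirectory of the output
directory and the run finishes with a JSON manifest recording the seed,
configuration hash, and per-stage cell counts (in/out of each filter).
A stage whose final artifact already exists is skipped when ``resume``
is set, so deleting one stage's outputs recomputes only that stage and
the ones after it.

Two data paths exist: with ``render_images`` the cohort is rasterized
and cells are re-extracted by the image pipeline (spillover compensation,
median filter, segmentation, artifact filter, quantification); without
it the generator's ground-truth cell table feeds phenotyping directly,
which is the fast path for statistics-level validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .config import PipelineConfig
from .io import read_roi_stack, write_json
from .panel import default_panel, write_panel_csv, write_spillover_csv
from .phenotyping import (
    annotate_clusters,
    cluster_cells,
    cluster_mean_heatmap,
    correct_batch,
    densities_per_mm2,
    transform_expression,
)
from .preprocess import compensate_spillover, denoise_median
from .segmentation import segment_roi
from .spatial import (
    aggregate_interactions,
    cluster_neighborhoods,
    interaction_permutation_test,
    knn_profiles,
    patch_distance_analysis,
)
from .clinical import abundance_clinical_matrix, compare_two_groups

logger = logging.getLogger(__name__)

STAGES = ["simulate", "segment", "phenotype", "spatial", "stats"]


class StageError(RuntimeError):
    def __init__(self, stage: str, path, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {path}: {cause}")
        self.stage = stage


def _spec_for(config: PipelineConfig) -> synthetic.CohortSpec:
    if config.preset == "desk":
        return synthetic.desk_spec(seed=config.seed)
    if config.preset == "study-scale":
        return synthetic.study_scale_spec(seed=config.seed)
    raise ValueError(f"unknown preset {config.preset!r}")


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = False) -> Path:
    """Run every stage; returns the output directory."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate_published_constants()
    panel = default_panel()
    spec = _spec_for(config)
    funnel: dict[str, int] = {}

    # ---- simulate -----------------------------------------------------
    sim_dir = out / "simulate"
    truth_path = sim_dir / "truth_cells.csv"
    if resume and truth_path.exists():
        logger.info("simulate: resuming from %s", truth_path)
        truth_cells = pd.read_csv(truth_path)
        clinical = pd.read_csv(sim_dir / "clinical.csv")
    else:
        sim_dir.mkdir(exist_ok=True)
        images, truth = synthetic.generate_cohort(
            spec,
            render=config.render_images,
            out_dir=sim_dir / "rois" if config.render_images else None,
        )
        truth_cells, clinical = truth.cells, truth.clinical
        truth_cells.to_csv(truth_path, index=False)
        clinical.to_csv(sim_dir / "clinical.csv", index=False)
        write_panel_csv(panel, sim_dir / "panel.csv")
        write_spillover_csv(spec.spillover, sim_dir / "spillover.csv")
        write_json(truth.manifest, sim_dir / "cohort_manifest.json")
    funnel["simulated_cells"] = len(truth_cells)

    # ---- preprocess + segment ----------------------------------------
    seg_dir = out / "segment"
    cells_path = seg_dir / "cells.csv"
    if resume and cells_path.exists():
        logger.info("segment: resuming from %s", cells_path)
        cells = pd.read_csv(cells_path)
    elif config.render_images:
        seg_dir.mkdir(exist_ok=True)
        frames = []
        rois = spec.rois()
        for _, roi in rois.iterrows():
            path = sim_dir / "rois" / f"{roi['roi_id']}.tiff"
            try:
                img = read_roi_stack(path, panel, pixel_size_um=spec.pixel_size_um)
                img = compensate_spillover(img, spec.spillover)
                img = denoise_median(img, size=config.median_kernel)
                _, table = segment_roi(
                    img,
                    panel,
                    max_centroid_dist_px=config.max_centroid_dist_px,
                    sample_id=roi["sample_id"],
                    roi_id=roi["roi_id"],
                )
                frames.append(table)
            except Exception as exc:  # halt with stage + input path
                raise StageError("segment", path, exc) from exc
        cells = pd.concat(frames, ignore_index=True)
        cells.to_csv(cells_path, index=False)
    else:
        # fast path: ground-truth cell table is already the quantified table
        seg_dir.mkdir(exist_ok=True)
        cells = truth_cells.copy()
        cells.to_csv(cells_path, index=False)
    funnel["segmented_cells"] = len(cells)

    # ---- phenotype ----------------------------------------------------
    phen_dir = out / "phenotype"
    annot_path = phen_dir / "annotated_cells.csv"
    if resume and annot_path.exists():
        logger.info("phenotype: resuming from %s", annot_path)
        cells = pd.read_csv(annot_path)
        densities = pd.read_csv(phen_dir / "densities.csv")
    else:
        phen_dir.mkdir(exist_ok=True)
        markers = [m for m in panel.markers if m in cells.columns]
        expr = transform_expression(cells, markers, config.cofactor, config.cap_percentile)
        expr = correct_batch(expr, cells["sample_id"].to_numpy(), mode=config.batch_mode)
        labels = cluster_cells(expr, config.cluster_k_graph, config.cluster_resolution,
                               seed=config.seed)
        annotation = annotate_clusters(expr, labels, spec.templates)
        cells = cells.copy()
        cells["cluster"] = labels
        cells["population"] = annotation.relabel(labels)
        cells.to_csv(annot_path, index=False)
        cluster_mean_heatmap(expr, labels).to_csv(phen_dir / "cluster_heatmap_z.csv")
        densities = densities_per_mm2(
            cells, spec.roi_area_mm2(), [t.name for t in spec.templates]
        )
        densities.to_csv(phen_dir / "densities.csv", index=False)
    funnel["annotated_cells"] = int((cells["population"] != "unassigned").sum())

    # ---- spatial ------------------------------------------------------
    spat_dir = out / "spatial"
    cn_path = spat_dir / "cn_assignments.csv"
    if resume and cn_path.exists():
        logger.info("spatial: resuming from %s", cn_path)
        cn_cells = pd.read_csv(cn_path)
    else:
        spat_dir.mkdir(exist_ok=True)
        annotated = cells[cells["population"] != "unassigned"]
        profiles = knn_profiles(annotated, k=config.knn_k)
        cn = cluster_neighborhoods(profiles, K=config.cn_k, seed=config.seed)
        cn_cells = profiles.cell_index.copy()
        cn_cells["cn"] = cn.labels
        cn_cells["cn_name"] = [cn.cn_names[c] for c in cn.labels]
        cn_cells.to_csv(cn_path, index=False)
        pd.DataFrame(cn.centroids, columns=cn.populations).to_csv(
            spat_dir / "cn_centroids.csv", index=False
        )
        per_roi = interaction_permutation_test(
            annotated, k=config.knn_k, n_perm=config.n_perm, seed=config.seed
        )
        per_roi.to_csv(spat_dir / "interactions_roi.csv", index=False)
        aggregate_interactions(per_roi).to_csv(spat_dir / "interactions_cohort.csv", index=False)
        patch_distance_analysis(annotated, bins=list(config.patch_bins)).to_csv(
            spat_dir / "patch_profiles.csv", index=False
        )

    # ---- stats --------------------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    dens_wide = (
        densities.pivot_table(index=["sample_id", "roi_id"], columns="population",
                              values="density_per_mm2", fill_value=0.0)
        .groupby("sample_id")
        .mean()
        .reset_index()
    )
    corr = abundance_clinical_matrix(dens_wide, clinical)
    corr.to_csv(stats_dir / "abundance_clinical.csv", index=False)

    groups = clinical.set_index("sample_id")["group"]
    comp_rows = []
    roi_dens = densities.pivot_table(index=["sample_id", "roi_id"], columns="population",
                                     values="density_per_mm2", fill_value=0.0).reset_index()
    roi_dens["group"] = roi_dens["sample_id"].map(groups)
    for pop in [t.name for t in spec.templates]:
        a = roi_dens.loc[roi_dens["group"] == "case", pop].to_numpy()
        b = roi_dens.loc[roi_dens["group"] == "control", pop].to_numpy()
        if len(a) >= 3 and len(b) >= 3:
            res = compare_two_groups(a, b)
            comp_rows.append(dict(population=pop, test=res.test_used,
                                  statistic=res.statistic, p=res.p,
                                  direction=res.direction))
    pd.DataFrame(comp_rows).to_csv(stats_dir / "group_comparisons.csv", index=False)

    # ---- manifest -----------------------------------------------------
    cfg_yaml = config.to_yaml()
    manifest = {
        "seed": config.seed,
        "preset": config.preset,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "config": json.loads(json.dumps(cfg_yaml)),
        "stages": STAGES,
        "cell_funnel": funnel,
    }
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    write_json(manifest, out / "run_manifest.json")
    (out / "config.yaml").write_text(cfg_yaml)
    return out
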