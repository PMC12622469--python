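#!/usr/bin/env python
"""Render a handful of ROIs and push them through the image pipeline.

Demonstrates the raw-image path on 4 ROIs of the simulated cohort:
rasterize -> spillover compensation -> 3x3 median filter -> segmentation
with the 15-px centroid-distance artifact filter -> per-cell
quantification, then compares recovered cell counts against the planted
ground truth. Summary lands in results/segmentation_summary.csv.

Run after 01_simulate_cohort.py.
"""

from pathlib import Path

import pandas as pd
from scipy.spatial import cKDTree

from nephroimc.panel import default_panel
from nephroimc.preprocess import compensate_spillover, denoise_median
from nephroimc.segmentation import segment_roi
from nephroimc.synthetic import desk_spec, render_roi, sample_expressions, simulate_points

RESULTS = Path("results")
SCRATCH = Path("scratch/segmentation")
SEED = 7
N_ROIS = 4


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    spec = desk_spec(seed=SEED)
    panel = default_panel()
    rois = spec.rois().head(N_ROIS)

    rows = []
    for _, roi in rois.iterrows():
        k = int(roi["roi_index"])
        pts, types, _ = simulate_points(spec, k)
        expr = sample_expressions(spec, types, k)
        img = render_roi(pts, types, spec, expressions=expr, roi_index=k)
        img = compensate_spillover(img, spec.spillover)
        img = denoise_median(img)
        _, table = segment_roi(img, panel, sample_id=roi["sample_id"], roi_id=roi["roi_id"])
        d, _ = cKDTree(pts).query(table[["x_px", "y_px"]].to_numpy())
        matched = int((d <= 3).sum())
        rows.append(
            dict(roi_id=roi["roi_id"], truth_cells=len(pts), segmented=len(table),
                 matched_within_3px=matched,
                 recall=round(matched / len(pts), 3),
                 precision=round(matched / max(len(table), 1), 3))
        )
        table.to_csv(SCRATCH / f"{roi['roi_id']}_cells.csv", index=False)

    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "segmentation_summary.csv", index=False)
    print(summary.to_string(index=False))
    print("\nNote: the desk cohort is dense (overlapping cells are allowed by the "
          "generator), so recall here sits below the >=0.9 achieved on "
          "non-overlapping fixtures — see tests/test_segmentation.py.")


if __name__ == "__main__":
    main()
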