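"""Shared fixtures: small synthetic cohorts and clean image fixtures.

Everything is generated programmatically at collection time; fixture
cohorts are deliberately small so the full suite runs on one CPU in
minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nephroimc.panel import default_panel
from nephroimc.preprocess import MultiChannelImage, SpilloverMatrix
from nephroimc.synthetic import (
    CohortSpec,
    default_templates,
    desk_spec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def tiny_spec(panel):
    """2+2 samples, 1 ROI each, 200x200 um, noise-free, no spillover.

    Densities are balanced (150 cells/mm^2 per population) so every
    population carries more cells than the kNN-graph degree and planted
    types are recoverable exactly.
    """
    from nephroimc.synthetic import PopulationTemplate

    templates = [
        PopulationTemplate(t.name, t.signature, {"control": 150.0, "case": 150.0},
                           t.nucleus_radius_px)
        for t in default_templates()
    ]
    return CohortSpec(
        n_control_samples=2,
        n_case_samples=2,
        rois_per_control=1,
        rois_per_case=1,
        roi_size_um=(200.0, 200.0),
        templates=templates,
        noise_cv=0.0,
        shot_noise=False,
        spillover=SpilloverMatrix.identity(default_panel().markers),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    _, truth = generate_cohort(tiny_spec)
    return truth


@pytest.fixture(scope="session")
def desk_truth():
    """Desk-preset cohort ground truth (seed 7), shared across tests."""
    _, truth = generate_cohort(desk_spec(seed=7))
    return truth


@pytest.fixture(scope="session")
def annotated_cells(desk_truth):
    """Ground-truth cell table with the population column spatial stats expect."""
    return desk_truth.cells.rename(columns={"type": "population"})


def grid_cell_image(panel, template, n_side=3, spacing_px=20, size_px=100):
    """Noise-free image with cells of one template on a regular grid.

    Cells are far apart (no overlap) so segmentation must recover the
    exact count; returns (image, true centers in px).
    """
    from nephroimc.synthetic import CohortSpec, render_roi
    from nephroimc.panel import default_panel

    centers = []
    for i in range(n_side):
        for j in range(n_side):
            centers.append((20 + j * spacing_px, 20 + i * spacing_px))
    points = np.array(centers, dtype=float)
    types = np.array([template.name] * len(points), dtype=object)
    spec = CohortSpec(
        n_control_samples=1,
        n_case_samples=1,
        rois_per_control=1,
        rois_per_case=1,
        roi_size_um=(float(size_px), float(size_px)),
        templates=[template],
        rules=[],
        noise_cv=0.0,
        shot_noise=False,
        spillover=SpilloverMatrix.identity(default_panel().markers),
        seed=0,
    )
    img = render_roi(points, types, spec, roi_index=0)
    return img, points


@pytest.fixture(scope="session")
def clean_grid(panel, templates):
    """9 well-separated resident macrophages, noise-free."""
    tmpl = [t for t in templates if t.name == "resident_macrophage"][0]
    return grid_cell_image(panel, tmpl)
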