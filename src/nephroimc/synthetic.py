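"""Synthetic IMC cohort generator with known ground truth.

The study design being emulated: kidney biopsies from 10 controls and 10
checkpoint-inhibitor nephrotoxicity (ICI-AN) cases, 4 ROIs per control and
8 per case (40 vs 80 ROIs), a 40-marker panel, 12 cell populations, and
clinical covariates (serum creatinine, eGFR, CRP, tubular injury index,
CXCL9) coupled to immune-cell density. Because the patient data are not
public, every downstream stage of the pipeline is validated against
cohorts drawn from this generator, where the answer is known.

Spatial structure
-----------------
* Baseline placement is a homogeneous Poisson process per population at
  its group-specific density.
* Attraction between populations is a Thomas-type cluster process: the
  coupled populations share Poisson-distributed cluster centres
  ("parents") and scatter around them with Gaussian offsets
  (sigma = radius/2), which preserves each population's marginal density.
* Repulsion is hard-core sequential placement: points of the second type
  are rejected within the hard-core radius of the first, with bounded
  retries.

Marker signal
-------------
Each cell draws its expression vector log-normally around its population
template (mean-preserving multiplicative noise, default CV 0.3). ROIs are
rendered by painting a nuclear disk plus membrane annulus per cell,
forward-applying the spillover matrix, and adding Poisson shot noise.
With noise disabled and identity spillover the rendered image quantifies
back to the template signature exactly, which anchors the round-trip tests.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelSpec, default_panel, default_spillover
from .preprocess import MultiChannelImage, SpilloverMatrix

__all__ = [
    "PopulationTemplate",
    "SpatialRule",
    "ClinicalModel",
    "CohortSpec",
    "GroundTruth",
    "SimulationError",
    "default_templates",
    "default_rules",
    "desk_spec",
    "study_scale_spec",
    "simulate_points",
    "render_roi",
    "synthesize_clinical",
    "sample_fibrosis",
    "generate_cohort",
    "sample_level_cohort",
    "POPULATIONS",
]

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """Raised when a point configuration cannot be realized."""


# the 12 populations, in the order they are reported
POPULATIONS = [
    "epithelial",
    "other_vimentin",
    "resident_macrophage",
    "cd8_t",
    "cd4_t",
    "granulocyte",
    "endothelial",
    "infiltrating_macrophage",
    "fibroblast",
    "b_cell",
    "cd169_macrophage",
    "dnt",
]

# populations whose densities drive the clinical covariates
DRIVER_POPULATIONS = ["resident_macrophage", "cd8_t", "fibroblast"]


@dataclass
class PopulationTemplate:
    """Mean marker signature and placement density for one population."""

    name: str
    signature: np.ndarray  # mean intensity per panel channel
    base_density: dict[str, float]  # cells/mm^2 per group ("control"/"case")
    nucleus_radius_px: int = 3

    def __post_init__(self) -> None:
        self.signature = np.asarray(self.signature, dtype=float)
        if (self.signature < 0).any():
            raise ValueError(f"{self.name}: signature must be nonnegative")
        for g, d in self.base_density.items():
            if d < 0:
                raise ValueError(f"{self.name}: density for {g!r} must be >= 0")
        if self.nucleus_radius_px < 1:
            raise ValueError(f"{self.name}: nucleus_radius_px must be >= 1")


@dataclass
class SpatialRule:
    """Pairwise placement rule between two populations."""

    type_a: str
    type_b: str
    mode: str  # attraction | repulsion | none
    strength: float = 0.0  # offspring per parent (attraction) — ignored for none
    radius_um: float = 15.0

    def __post_init__(self) -> None:
        if self.mode not in ("attraction", "repulsion", "none"):
            raise ValueError(f"unknown rule mode {self.mode!r}")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.strength < 0:
            raise ValueError("strength must be nonnegative")


@dataclass
class ClinicalModel:
    """Linear maps from planted cell densities to clinical covariates.

    Each covariate is intercept + sum(coef * density) + Gaussian noise;
    densities are per-sample means in cells/mm^2. Urinary CXCL9 depends on
    resident-macrophage density only, mirroring its role as a macrophage
    activity marker; eGFR decreases with the immune/stromal burden.
    """

    coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "serum_cr": {"intercept": 55.0, "resident_macrophage": 0.05, "cd8_t": 0.05, "fibroblast": 0.05},
            "egfr": {"intercept": 115.0, "resident_macrophage": -0.045, "cd8_t": -0.045, "fibroblast": -0.045},
            "crp": {"intercept": 1.0, "resident_macrophage": 0.012, "cd8_t": 0.012, "fibroblast": 0.012},
            "tii": {"intercept": -0.2, "resident_macrophage": 0.0022, "cd8_t": 0.0022, "fibroblast": 0.0022},
            "cxcl9_urine": {"intercept": 5.0, "resident_macrophage": 0.6},
            "cxcl9_serum": {"intercept": 20.0, "resident_macrophage": 0.25, "cd8_t": 0.25},
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "serum_cr": 8.0,
            "egfr": 6.0,
            "crp": 1.5,
            "tii": 0.25,
            "cxcl9_urine": 20.0,
            "cxcl9_serum": 15.0,
        }
    )

    def without_noise(self) -> "ClinicalModel":
        return ClinicalModel(self.coefficients, {k: 0.0 for k in self.noise_sd})


def default_templates(panel: PanelSpec | None = None) -> list[PopulationTemplate]:
    """The 12 default population templates over the 40-marker panel.

    Signatures are arbitrary-unit mean intensities: every population is
    DNA-positive, and each carries one defining marker whose value tops
    its signature (pairwise-distinct argmax), plus supporting lineage
    markers at intermediate levels. Densities (cells/mm^2) differ by
    group: immune and stromal populations are enriched in the case group,
    epithelium is mildly reduced — the infiltration pattern the analysis
    is meant to detect.
    """
    panel = panel or default_panel()
    markers = panel.markers
    idx = {m: i for i, m in enumerate(markers)}

    base = np.zeros(len(markers))
    base[idx["DNA1"]] = 8.0
    base[idx["DNA2"]] = 8.0
    base[idx["HistoneH3"]] = 5.0

    def sig(**levels: float) -> np.ndarray:
        s = base.copy()
        s += 0.2  # faint nonspecific background on every channel
        for m, v in levels.items():
            s[idx[m]] = v
        return s

    specs: list[tuple[str, np.ndarray, float, float, int]] = [
        # name, signature, control density, case density, nucleus radius
        ("epithelial", sig(AQP1=10, PanCK=6, ECadherin=6, THP=3, Calbindin=3), 1500, 1200, 4),
        ("other_vimentin", sig(Vimentin=10, PDL1=1), 600, 600, 3),
        ("resident_macrophage", sig(CX3CR1=10, CD68=8, CD45=6, CD163=5, HLADR=4, CD40=2, IL1b=1.5), 250, 700, 3),
        ("cd8_t", sig(CD8a=10, CD3=8, CD45=7, GranzymeB=3, PD1=2), 80, 350, 2),
        ("cd4_t", sig(CD4=10, CD3=8, CD45=7, FoxP3=1.5), 60, 200, 2),
        ("granulocyte", sig(CD15=10, MPO=8, CD11b=5, CD45=6), 40, 120, 2),
        ("endothelial", sig(CD31=10, Vimentin=4), 300, 300, 3),
        ("infiltrating_macrophage", sig(CD14=10, CD68=7, CD11b=6, CD45=6, CD16=4, HLADR=3), 50, 250, 3),
        ("fibroblast", sig(CollagenI=10, SMA=7, Vimentin=5, MMP12=2), 100, 400, 3),
        ("b_cell", sig(CD20=10, CD45=7, HLADR=5), 20, 100, 2),
        ("cd169_macrophage", sig(CD169=10, CD68=7, CD45=6, HLADR=3), 15, 80, 3),
        ("dnt", sig(CD3=10, CD45=7), 10, 60, 2),
    ]
    templates = [
        PopulationTemplate(name, s, {"control": dc, "case": dk}, r)
        for name, s, dc, dk, r in specs
    ]
    argmaxes = [int(np.argmax(t.signature)) for t in templates]
    assert len(set(argmaxes)) == len(templates), "templates must have distinct argmax markers"
    return templates


def default_rules() -> list[SpatialRule]:
    """Planted attraction among resident macrophages, CD8 T cells and
    fibroblasts — the immune-stromal niche the neighborhood analysis
    should rediscover."""
    trio = ["resident_macrophage", "cd8_t", "fibroblast"]
    rules = []
    for i in range(len(trio)):
        for j in range(i + 1, len(trio)):
            rules.append(SpatialRule(trio[i], trio[j], "attraction", strength=8.0, radius_um=15.0))
    return rules


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the seed makes it a program."""

    n_control_samples: int = 10
    n_case_samples: int = 10
    rois_per_control: int = 4
    rois_per_case: int = 8
    roi_size_um: tuple[float, float] = (600.0, 600.0)
    pixel_size_um: float = 1.0
    templates: list[PopulationTemplate] = field(default_factory=default_templates)
    rules: list[SpatialRule] = field(default_factory=default_rules)
    spillover: SpilloverMatrix = field(default_factory=default_spillover)
    fibrosis_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (5.60, 1.4), "case": (24.27, 5.68)}
    )
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    noise_cv: float = 0.3  # log-normal marker noise, coefficient of variation
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.n_control_samples, self.n_case_samples, self.rois_per_control, self.rois_per_case):
            if v < 1:
                raise ValueError("sample and ROI counts must be positive")
        if min(self.roi_size_um) <= 0 or self.pixel_size_um <= 0:
            raise ValueError("ROI size and pixel size must be positive")
        for g, (m, s) in self.fibrosis_mean_sd.items():
            if s < 0:
                raise ValueError(f"fibrosis SD for {g!r} must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        names = [t.name for t in self.templates]
        if len(set(names)) != len(names):
            raise ValueError("template names must be unique")

    # ---- cohort layout ------------------------------------------------
    def samples(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_control_samples):
            rows.append({"sample_id": f"C{i + 1:02d}", "group": "control"})
        for i in range(self.n_case_samples):
            rows.append({"sample_id": f"P{i + 1:02d}", "group": "case"})
        return pd.DataFrame(rows)

    def rois(self) -> pd.DataFrame:
        """One row per ROI: global roi_index, roi_id, sample, group."""
        rows = []
        k = 0
        for _, s in self.samples().iterrows():
            n = self.rois_per_control if s["group"] == "control" else self.rois_per_case
            for r in range(n):
                rows.append(
                    {
                        "roi_index": k,
                        "roi_id": f"{s['sample_id']}_roi{r + 1}",
                        "sample_id": s["sample_id"],
                        "group": s["group"],
                    }
                )
                k += 1
        return pd.DataFrame(rows)

    @property
    def n_rois(self) -> int:
        return (
            self.n_control_samples * self.rois_per_control
            + self.n_case_samples * self.rois_per_case
        )

    def roi_area_mm2(self) -> float:
        return self.roi_size_um[0] * self.roi_size_um[1] / 1e6

    def template(self, name: str) -> PopulationTemplate:
        for t in self.templates:
            if t.name == name:
                return t
        raise KeyError(f"no template named {name!r}")


def desk_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Reduced preset: 4+4 samples, 300x300 um ROIs — minutes, not hours."""
    kw = dict(
        n_control_samples=4,
        n_case_samples=4,
        roi_size_um=(300.0, 300.0),
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def study_scale_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Study-design preset: 10+10 samples, 40 vs 80 ROIs, 1 mm^2 ROIs."""
    kw = dict(roi_size_um=(1000.0, 1000.0), seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


# ---------------------------------------------------------------------------
# point placement
# ---------------------------------------------------------------------------


def _rng(spec: CohortSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, *stream]))


def _attraction_groups(rules: list[SpatialRule]) -> list[tuple[set[str], float, float]]:
    """Union attraction rules into groups sharing one parent process.

    Returns (member types, mean strength, mean radius) per group.
    """
    groups: list[set[str]] = []
    params: list[list[tuple[float, float]]] = []
    for r in rules:
        if r.mode != "attraction":
            continue
        hit = [i for i, g in enumerate(groups) if r.type_a in g or r.type_b in g]
        if not hit:
            groups.append({r.type_a, r.type_b})
            params.append([(r.strength, r.radius_um)])
        else:
            keep = hit[0]
            groups[keep] |= {r.type_a, r.type_b}
            params[keep].append((r.strength, r.radius_um))
            for i in sorted(hit[1:], reverse=True):
                groups[keep] |= groups.pop(i)
                params[keep].extend(params.pop(i))
    out = []
    for g, ps in zip(groups, params):
        s = float(np.mean([p[0] for p in ps]))
        rad = float(np.mean([p[1] for p in ps]))
        out.append((g, s, rad))
    return out


def simulate_points(
    spec: CohortSpec, roi_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place cells in one ROI.

    Returns
    -------
    points : (n, 2) float array, positions in um within the ROI rectangle
    types : (n,) object array of population names
    planted_cn : (n,) object array — attraction-group tag per cell
        ("none" for cells placed by the baseline Poisson process)

    Raises
    ------
    SimulationError
        When a hard-core repulsion rule cannot place its points after
        bounded retries.
    """
    rois = spec.rois()
    if not 0 <= roi_index < len(rois):
        raise IndexError(f"roi_index {roi_index} outside cohort of {len(rois)} ROIs")
    group = rois.iloc[roi_index]["group"]
    rng = _rng(spec, roi_index, 0)
    W, H = spec.roi_size_um
    area_mm2 = spec.roi_area_mm2()

    attraction = _attraction_groups(spec.rules)
    attracted_types = set().union(*(g for g, _, _ in attraction)) if attraction else set()
    repulsion = [r for r in spec.rules if r.mode == "repulsion"]
    repelled_types = {r.type_b for r in repulsion} | {r.type_a for r in repulsion}
    overlap = attracted_types & repelled_types
    if overlap:
        raise ValueError(f"types {sorted(overlap)} appear in both attraction and repulsion rules")

    pts: list[np.ndarray] = []
    typ: list[str] = []
    cn: list[str] = []

    def add(points: np.ndarray, name: str, tag: str) -> None:
        for p in points:
            pts.append(p)
            typ.append(name)
            cn.append(tag)

    # Thomas-process groups: shared parents, Gaussian offspring
    for members, strength, radius in attraction:
        tag = "+".join(sorted(members))
        expected_total = sum(
            spec.template(m).base_density.get(group, 0.0) * area_mm2 for m in members
        )
        if expected_total <= 0:
            continue
        strength = max(strength, 1e-6)
        n_parents = max(1, rng.poisson(expected_total / strength))
        parents = rng.uniform([0, 0], [W, H], size=(n_parents, 2))
        sigma = radius / 2.0
        for m in sorted(members):
            lam = spec.template(m).base_density.get(group, 0.0) * area_mm2
            n = rng.poisson(lam)
            if n == 0:
                continue
            parent_idx = rng.integers(0, n_parents, size=n)
            offsets = rng.normal(0.0, sigma, size=(n, 2))
            p = parents[parent_idx] + offsets
            p[:, 0] = np.clip(p[:, 0], 0.0, np.nextafter(W, 0))
            p[:, 1] = np.clip(p[:, 1], 0.0, np.nextafter(H, 0))
            add(p, m, tag)

    # hard-core sequential placement for repelled types
    placed_for_repulsion: dict[str, np.ndarray] = {}
    for r in repulsion:
        for name in dict.fromkeys([r.type_a, r.type_b]):  # A first, preserve order
            if name in placed_for_repulsion:
                continue
            lam = spec.template(name).base_density.get(group, 0.0) * area_mm2
            n = rng.poisson(lam)
            accepted: list[np.ndarray] = []
            # anchors this type must keep distance from
            anchors = []
            for rr in repulsion:
                if rr.type_b == name and rr.type_a in placed_for_repulsion:
                    anchors.append((placed_for_repulsion[rr.type_a], rr.radius_um))
                if rr.type_a == rr.type_b == name:
                    anchors.append((None, rr.radius_um))  # self hard-core
            max_tries = 200
            for _ in range(n):
                for attempt in range(max_tries):
                    cand = rng.uniform([0, 0], [W, H])
                    ok = True
                    for pts_a, rad in anchors:
                        ref = np.array(accepted) if pts_a is None else pts_a
                        if len(ref) and np.min(np.linalg.norm(ref - cand, axis=1)) < rad:
                            ok = False
                            break
                    if ok:
                        accepted.append(cand)
                        break
                else:
                    raise SimulationError(
                        f"could not place {name!r} under hard-core constraints "
                        f"after {max_tries} retries (density too high for radius)"
                    )
            arr = np.array(accepted).reshape(-1, 2)
            placed_for_repulsion[name] = arr
            add(arr, name, "none")

    # everything else: homogeneous Poisson
    for t in spec.templates:
        if t.name in attracted_types or t.name in placed_for_repulsion:
            continue
        lam = t.base_density.get(group, 0.0) * area_mm2
        n = rng.poisson(lam)
        if n:
            add(rng.uniform([0, 0], [W, H], size=(n, 2)), t.name, "none")

    if not pts:
        return np.zeros((0, 2)), np.array([], dtype=object), np.array([], dtype=object)
    order = np.lexsort((np.array(pts)[:, 1], np.array(pts)[:, 0]))
    points = np.array(pts)[order]
    return points, np.array(typ, dtype=object)[order], np.array(cn, dtype=object)[order]


# ---------------------------------------------------------------------------
# expression sampling and rendering
# ---------------------------------------------------------------------------


def sample_expressions(
    spec: CohortSpec, types: np.ndarray, roi_index: int
) -> np.ndarray:
    """Draw per-cell marker vectors log-normally around the templates.

    The multiplicative noise is mean-preserving: E[expr] equals the
    template signature for any CV. noise_cv = 0 returns the signatures.
    """
    rng = _rng(spec, roi_index, 1)
    n_markers = len(spec.templates[0].signature)
    out = np.zeros((len(types), n_markers))
    sig_by_name = {t.name: t.signature for t in spec.templates}
    cv = spec.noise_cv
    if cv > 0:
        s2 = np.log1p(cv**2)
        mult = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=out.shape)
    else:
        mult = np.ones(out.shape)
    for i, t in enumerate(types):
        out[i] = sig_by_name[t] * mult[i]
    return out


def _disk_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = xx**2 + yy**2 <= r**2
    return np.stack([yy[keep], xx[keep]], axis=1)


def render_roi(
    points: np.ndarray,
    types: np.ndarray,
    spec: CohortSpec,
    expressions: np.ndarray | None = None,
    roi_index: int = 0,
) -> MultiChannelImage:
    """Rasterize one ROI into a multi-channel image.

    Each cell is painted as a nucleus disk (template nucleus radius) plus
    a 2-px membrane annulus; non-nuclear channels are painted uniformly
    over the whole footprint at the cell's expression value, and
    nuclear-role channels inside the nucleus only, scaled by the
    footprint/nucleus pixel ratio so that the mean over the footprint
    equals the expression value on every channel. Spillover is then
    forward-applied and Poisson shot noise added (if enabled).
    """
    panel = default_panel()
    markers = panel.markers
    if spec.templates and len(spec.templates[0].signature) != len(markers):
        markers = [f"ch{i}" for i in range(len(spec.templates[0].signature))]
    px = spec.pixel_size_um
    W_px = int(round(spec.roi_size_um[0] / px))
    H_px = int(round(spec.roi_size_um[1] / px))
    C = len(markers)
    data = np.zeros((H_px, W_px, C))

    if len(points) and (points.min() < 0 or (points[:, 0] >= spec.roi_size_um[0]).any() or (points[:, 1] >= spec.roi_size_um[1]).any()):
        raise ValueError("all points must lie inside the ROI")

    if expressions is None:
        expressions = sample_expressions(spec, types, roi_index)

    nuclear_idx = np.array(
        [i for i, m in enumerate(markers) if m in set(panel.nuclear_markers)], dtype=int
    )
    other_idx = np.array([i for i in range(C) if i not in set(nuclear_idx)], dtype=int)

    radius_by_name = {t.name: t.nucleus_radius_px for t in spec.templates}
    membrane_width = 2
    for i, (pt, name) in enumerate(zip(points, types)):
        r_n = radius_by_name[name]
        r_f = r_n + membrane_width
        cx = int(pt[0] / px)
        cy = int(pt[1] / px)
        nuc = _disk_offsets(r_n) + [cy, cx]
        foot = _disk_offsets(r_f) + [cy, cx]

        def clip(offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            keep = (
                (offsets[:, 0] >= 0)
                & (offsets[:, 0] < H_px)
                & (offsets[:, 1] >= 0)
                & (offsets[:, 1] < W_px)
            )
            return offsets[keep, 0], offsets[keep, 1]

        ny, nx = clip(nuc)
        fy, fx = clip(foot)
        if len(fy) == 0:
            continue
        expr = expressions[i]
        data[fy[:, None], fx[:, None], other_idx[None, :]] += expr[other_idx]
        if len(ny) and len(nuclear_idx):
            scale = len(fy) / len(ny)
            data[ny[:, None], nx[:, None], nuclear_idx[None, :]] += expr[nuclear_idx] * scale

    # forward spillover: observed = true @ S
    S = spec.spillover
    if S is not None and S.n_channels == C:
        data = data.reshape(-1, C) @ S.values
        data = data.reshape(H_px, W_px, C)

    if spec.shot_noise:
        rng = _rng(spec, roi_index, 2)
        data = rng.poisson(np.clip(data, 0, None) * 4.0) / 4.0  # sub-integer shot noise
        data = data.astype(float)

    return MultiChannelImage(data, markers, pixel_size_um=px)


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------


def sample_fibrosis(spec: CohortSpec, group: str, rng: np.random.Generator) -> float:
    """Draw one sample-level fibrosis area fraction (%), truncated to [0, 100]."""
    mean, sd = spec.fibrosis_mean_sd[group]
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 100.0:
            return float(v)
    return float(np.clip(mean, 0.0, 100.0))


def synthesize_clinical(
    spec: CohortSpec, per_sample_densities: pd.DataFrame
) -> pd.DataFrame:
    """Generate the clinical table from planted per-sample densities.

    Parameters
    ----------
    per_sample_densities
        One row per sample with columns ``sample_id``, ``group`` and one
        density column (cells/mm^2) per population the clinical model
        references.

    Returns
    -------
    DataFrame with sample_id, group, serum_cr, egfr, crp, tii,
    cxcl9_urine, cxcl9_serum, fibrosis_pct. Negative generated
    concentrations are clipped to 0 (warning); TII is clipped into [0, 5].
    """
    model = spec.clinical_model
    rng = _rng(spec, 1_000_003)
    rows = []
    clipped = 0
    for _, s in per_sample_densities.iterrows():
        rec = {"sample_id": s["sample_id"], "group": s["group"]}
        for var, coefs in model.coefficients.items():
            val = coefs.get("intercept", 0.0)
            for pop, c in coefs.items():
                if pop == "intercept":
                    continue
                val += c * float(s[pop])
            sd = model.noise_sd.get(var, 0.0)
            if sd > 0:
                val += rng.normal(0.0, sd)
            if var == "tii":
                val = float(np.clip(val, 0.0, 5.0))
            elif var == "egfr":
                val = max(val, 1.0)
            elif val < 0:
                clipped += 1
                val = 0.0
            rec[var] = float(val)
        rec["fibrosis_pct"] = sample_fibrosis(spec, s["group"], rng)
        rows.append(rec)
    if clipped:
        warnings.warn(f"{clipped} generated concentrations were negative and clipped to 0")
    return pd.DataFrame(rows)


def sample_level_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate only the sample-level layer of a cohort.

    Draws per-ROI, per-population cell counts from the same Poisson law
    the spatial placement uses (without laying out positions), averages
    them into per-sample densities, and synthesizes the clinical table.
    This is the fast path for calibration studies that need many cohorts
    but no spatial coordinates.

    Returns (per_sample_densities, clinical).
    """
    rois = spec.rois()
    area = spec.roi_area_mm2()
    rows = []
    for _, roi in rois.iterrows():
        rng = _rng(spec, int(roi["roi_index"]), 3)
        rec = {"sample_id": roi["sample_id"], "group": roi["group"], "roi_id": roi["roi_id"]}
        for t in spec.templates:
            lam = t.base_density.get(roi["group"], 0.0) * area
            rec[t.name] = rng.poisson(lam) / area
        rows.append(rec)
    per_roi = pd.DataFrame(rows)
    per_sample = (
        per_roi.drop(columns="roi_id").groupby(["sample_id", "group"]).mean().reset_index()
    )
    clinical = synthesize_clinical(spec, per_sample)
    return per_sample, clinical


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the generator knows about a cohort."""

    cells: pd.DataFrame  # roi_id, sample_id, group, cell_id, x_um, y_um, type, planted_cn (+ marker columns)
    clinical: pd.DataFrame
    manifest: dict

    def per_sample_densities(self, roi_area_mm2: float) -> pd.DataFrame:
        """Mean per-population density (cells/mm^2) per sample from truth."""
        counts = (
            self.cells.groupby(["sample_id", "group", "roi_id", "type"], observed=True)
            .size()
            .unstack("type", fill_value=0)
        )
        dens = counts / roi_area_mm2
        out = dens.groupby(["sample_id", "group"]).mean().reset_index()
        return out


def generate_cohort(
    spec: CohortSpec,
    render: bool = False,
    out_dir=None,
    with_expression: bool = True,
) -> tuple[list, GroundTruth]:
    """Generate a full synthetic cohort.

    Parameters
    ----------
    spec
        Cohort description including the seed; identical specs give
        byte-identical ground truth.
    render
        Rasterize per-ROI multi-channel images. Off by default: most
        validation paths consume the ground-truth cell table directly,
        and rendering dominates runtime.
    out_dir
        When given with ``render=True``, images are written as multi-page
        TIFFs under this directory (one file per ROI) and the returned
        image list holds file paths instead of in-memory arrays.
    with_expression
        Attach per-cell sampled marker vectors (one column per marker) to
        the cell table.

    Returns
    -------
    (images, GroundTruth) — ``images`` is empty when ``render=False``.
    """
    rois = spec.rois()
    panel = default_panel()
    markers = panel.markers
    images: list = []
    frames = []
    for _, roi in rois.iterrows():
        k = int(roi["roi_index"])
        points, types, cn = simulate_points(spec, k)
        expr = sample_expressions(spec, types, k) if (with_expression or render) else None
        df = pd.DataFrame(
            {
                "sample_id": roi["sample_id"],
                "roi_id": roi["roi_id"],
                "group": roi["group"],
                "cell_id": np.arange(len(points)),
                "x_um": points[:, 0] if len(points) else np.array([]),
                "y_um": points[:, 1] if len(points) else np.array([]),
                "type": types,
                "planted_cn": cn,
            }
        )
        if with_expression and expr is not None and len(spec.templates[0].signature) == len(markers):
            for j, m in enumerate(markers):
                df[m] = expr[:, j] if len(points) else np.array([])
        frames.append(df)
        if render:
            img = render_roi(points, types, spec, expressions=expr, roi_index=k)
            if out_dir is not None:
                from .io import write_roi_stack

                path = str(out_dir) + f"/{roi['roi_id']}.tiff"
                write_roi_stack(img, path)
                images.append(path)
            else:
                images.append(img)

    cells = pd.concat(frames, ignore_index=True)
    dens = (
        cells.groupby(["sample_id", "group", "roi_id", "type"], observed=True)
        .size()
        .unstack("type", fill_value=0)
        .reindex(columns=[t.name for t in spec.templates], fill_value=0)
        / spec.roi_area_mm2()
    )
    per_sample = dens.groupby(["sample_id", "group"]).mean().reset_index()
    clinical = synthesize_clinical(spec, per_sample)

    digest = hashlib.sha256(
        (cells.to_csv(index=False) + clinical.to_csv(index=False)).encode()
    ).hexdigest()
    manifest = {
        "seed": spec.seed,
        "n_samples": {"control": spec.n_control_samples, "case": spec.n_case_samples},
        "n_rois": {"control": int((rois["group"] == "control").sum()),
                   "case": int((rois["group"] == "case").sum())},
        "roi_size_um": list(spec.roi_size_um),
        "n_cells": int(len(cells)),
        "rendered": bool(render),
        "ground_truth_sha256": digest,
    }
    truth = GroundTruth(cells=cells, clinical=clinical, manifest=manifest)
    return images, truth
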