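"""Pipeline configuration with provenance-tagged numeric constants.

Every tunable of the pipeline lives here. Constants printed in the study
are tagged ``published`` and shipped in a read-only profile so accidental
drift is detectable by test; everything else is tagged ``default`` (a
package choice, freely configurable).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from types import MappingProxyType

import yaml

__all__ = ["PipelineConfig", "PUBLISHED_DEFAULTS"]

# study-printed constants: name -> value
PUBLISHED_DEFAULTS = MappingProxyType(
    {
        "max_centroid_dist_px": 15.0,
        "cap_percentile": 99.0,
        "knn_k": 10,
        "cn_k": 15,
        "patch_bins": ((0.0, 10.0), (10.0, 20.0), (20.0, 30.0)),
        "de_fc_thresh": 1.5,
        "de_fdr_thresh": 0.05,
        "n_panel_channels": 40,
        "n_populations": 12,
    }
)


@dataclass
class PipelineConfig:
    """All pipeline tunables; see each stage's module for semantics."""

    # preprocess
    contrast_low_pct: float = 1.0
    contrast_high_pct: float = 99.0
    median_kernel: int = 3
    # segmentation
    max_centroid_dist_px: float = 15.0  # published
    min_component_px: int = 9
    # phenotyping
    cofactor: float = 5.0
    cap_percentile: float = 99.0  # published
    cluster_k_graph: int = 30
    cluster_resolution: float = 1.0
    batch_mode: str = "median"
    # spatial
    knn_k: int = 10  # published
    cn_k: int = 15  # published
    n_perm: int = 1000
    patch_bins: tuple = ((0.0, 10.0), (10.0, 20.0), (20.0, 30.0))  # published
    # clinical
    de_fc_thresh: float = 1.5  # published
    de_fdr_thresh: float = 0.05  # published
    dispatch_alpha: float = 0.05
    # cohort / run
    preset: str = "desk"  # desk | study-scale
    render_images: bool = False
    seed: int = 0

    def provenance(self) -> dict[str, str]:
        """Provenance tag per field: 'published' for printed constants."""
        return {f.name: ("published" if f.name in PUBLISHED_DEFAULTS else "default") for f in fields(self)}

    def validate_published_constants(self) -> None:
        """Raise if a published-tagged constant drifted from the printed value."""
        for name, expected in PUBLISHED_DEFAULTS.items():
            if not hasattr(self, name):
                continue
            got = getattr(self, name)
            if isinstance(expected, tuple):
                got = tuple(tuple(b) for b in got)
            if got != expected:
                raise ValueError(
                    f"published-tagged constant {name} = {got!r}, expected {expected!r}"
                )

    # ---- round trip ---------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        d["patch_bins"] = [list(b) for b in d["patch_bins"]]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "patch_bins" in d:
            d["patch_bins"] = tuple(tuple(float(x) for x in b) for b in d["patch_bins"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())
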