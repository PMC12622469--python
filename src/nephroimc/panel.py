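"""Antibody panel description: channel order, metal tags, marker roles.

The default panel carries 40 metal-conjugated antibodies covering renal
structural markers (AQP1 for proximal tubule, THP for the thick ascending
limb, Calbindin for distal tubule, Vimentin for glomeruli), immune lineage
markers (CD45, CD3, CD4, CD8a, CD20, CD68, CX3CR1, CD169, ...) and
functional markers (Granzyme B, Ki-67, IL-1b, IDO-1, ...), plus iridium
DNA intercalator channels used for nuclear segmentation.

Roles
-----
nuclear
    DNA intercalator / histone channels; positive in every nucleus, used
    to seed segmentation.
membrane
    Broad surface markers (CD45, CD68, CD3, CD31, E-Cadherin) whose
    max-projection outlines cell borders for territory assignment.
structural
    Tissue-architecture markers used for compartment annotation.
phenotype
    Lineage / activation markers used for clustering and annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import SpilloverMatrix

__all__ = [
    "PanelSpec",
    "default_panel",
    "default_spillover",
    "read_panel_csv",
    "write_panel_csv",
    "read_spillover_csv",
    "write_spillover_csv",
]

_ROLES = ("nuclear", "membrane", "phenotype", "structural")

# (metal tag, marker, role) in channel (mass) order
_DEFAULT_PANEL: list[tuple[str, str, str]] = [
    ("In113", "HistoneH3", "nuclear"),
    ("La139", "CD15", "phenotype"),
    ("Ce140", "MMP12", "phenotype"),
    ("Pr141", "SMA", "structural"),
    ("Nd142", "PD1", "phenotype"),
    ("Nd143", "Vimentin", "structural"),
    ("Nd144", "CD14", "phenotype"),
    ("Nd145", "CD138", "phenotype"),
    ("Nd146", "CD16", "phenotype"),
    ("Sm147", "CD163", "phenotype"),
    ("Nd148", "PanCK", "structural"),
    ("Sm149", "AQP1", "structural"),
    ("Nd150", "PDL1", "phenotype"),
    ("Eu151", "CD31", "membrane"),
    ("Sm152", "CD45", "membrane"),
    ("Eu153", "CD4", "phenotype"),
    ("Sm154", "THP", "structural"),
    ("Gd155", "FoxP3", "phenotype"),
    ("Gd156", "CD11c", "phenotype"),
    ("Gd158", "CX3CR1", "phenotype"),
    ("Tb159", "CD68", "membrane"),
    ("Gd160", "CD20", "phenotype"),
    ("Dy161", "Calbindin", "structural"),
    ("Dy162", "CD8a", "phenotype"),
    ("Dy163", "CD11b", "phenotype"),
    ("Dy164", "CD169", "phenotype"),
    ("Ho165", "CD40", "phenotype"),
    ("Er166", "MPO", "phenotype"),
    ("Er167", "GranzymeB", "phenotype"),
    ("Er168", "Ki67", "phenotype"),
    ("Tm169", "CollagenI", "structural"),
    ("Er170", "CD3", "membrane"),
    ("Yb171", "HLADR", "phenotype"),
    ("Yb172", "IL1b", "phenotype"),
    ("Yb173", "IDO1", "phenotype"),
    ("Yb174", "ECadherin", "membrane"),
    ("Lu175", "HLAABC", "phenotype"),
    ("Yb176", "TNFa", "phenotype"),
    ("Ir191", "DNA1", "nuclear"),
    ("Ir193", "DNA2", "nuclear"),
]


@dataclass
class PanelSpec:
    """Ordered antibody panel: one row per acquisition channel."""

    table: pd.DataFrame  # columns: channel, metal, marker, role

    def __post_init__(self) -> None:
        required = {"channel", "metal", "marker", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns {sorted(missing)}")
        ch = self.table["channel"].to_numpy()
        if not np.array_equal(ch, np.arange(len(ch))):
            raise ValueError("channel indices must be contiguous from 0")
        if self.table["marker"].duplicated().any():
            dup = self.table.loc[self.table["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker names: {dup}")
        bad = set(self.table["role"]) - set(_ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}; allowed: {_ROLES}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def markers_with_role(self, role: str) -> list[str]:
        if role not in _ROLES:
            raise ValueError(f"unknown role {role!r}")
        return self.table.loc[self.table["role"] == role, "marker"].tolist()

    @property
    def nuclear_markers(self) -> list[str]:
        return self.markers_with_role("nuclear")

    @property
    def membrane_markers(self) -> list[str]:
        return self.markers_with_role("membrane")

    def index_of(self, marker: str) -> int:
        rows = self.table.index[self.table["marker"] == marker]
        if len(rows) == 0:
            raise KeyError(f"marker {marker!r} not in panel")
        return int(self.table.loc[rows[0], "channel"])

    def masses(self) -> np.ndarray:
        """Isotope mass number per channel, parsed from the metal tag."""
        return np.array(
            [int("".join(c for c in m if c.isdigit())) for m in self.table["metal"]]
        )


def default_panel() -> PanelSpec:
    """The 40-antibody kidney IMC panel used throughout the package."""
    table = pd.DataFrame(
        {
            "channel": range(len(_DEFAULT_PANEL)),
            "metal": [m for m, _, _ in _DEFAULT_PANEL],
            "marker": [mk for _, mk, _ in _DEFAULT_PANEL],
            "role": [r for _, _, r in _DEFAULT_PANEL],
        }
    )
    return PanelSpec(table)


def default_spillover(
    panel: PanelSpec | None = None,
    next_mass: float = 0.03,
    prev_mass: float = 0.01,
) -> SpilloverMatrix:
    """Nearest-mass crosstalk matrix.

    Isotope impurity leaks mostly into the M+1 channel (default 3%) with a
    smaller M-1 component (default 1%); channels whose mass neighbours are
    absent from the panel receive nothing. Published spillover matrices for
    lanthanide panels sit in this 1-5% range; the exact magnitudes here are
    a package default, not a measured matrix.
    """
    panel = panel or default_panel()
    masses = panel.masses()
    C = len(panel)
    S = np.eye(C)
    for i in range(C):
        for j in range(C):
            if i == j:
                continue
            if masses[j] == masses[i] + 1:
                S[i, j] = next_mass
            elif masses[j] == masses[i] - 1:
                S[i, j] = prev_mass
    return SpilloverMatrix(S, panel.markers)


def write_panel_csv(panel: PanelSpec, path) -> None:
    panel.table.to_csv(path, index=False)


def read_panel_csv(path) -> PanelSpec:
    return PanelSpec(pd.read_csv(path))


def write_spillover_csv(S: SpilloverMatrix, path) -> None:
    df = pd.DataFrame(S.values, index=S.channel_names, columns=S.channel_names)
    df.to_csv(path)


def read_spillover_csv(path) -> SpilloverMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("spillover CSV must have identical row and column channel names")
    return SpilloverMatrix(df.to_numpy(), list(df.columns))
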