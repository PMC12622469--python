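"""File formats: multi-page TIFF ROI stacks, label masks, tables.

Channel order on disk always equals panel order (one TIFF page per
channel). Pixel size is taken from TIFF resolution metadata when present
and falls back to the configured value (1 um default for IMC).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .panel import PanelSpec
from .preprocess import MultiChannelImage
from .segmentation import LabelMask

__all__ = [
    "read_roi_stack",
    "write_roi_stack",
    "write_label_mask",
    "read_label_mask",
    "write_json",
]


def write_roi_stack(img: MultiChannelImage, path) -> None:
    """Write a ROI as a multi-page float32 TIFF, one page per channel."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(img.data.astype(np.float32), 2, 0)  # (C, H, W)
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        metadata={"axes": "CYX", "channel_names": list(img.channel_names),
                  "pixel_size_um": img.pixel_size_um},
    )


def read_roi_stack(path, panel: PanelSpec, pixel_size_um: float = 1.0) -> MultiChannelImage:
    """Read a multi-page TIFF against a panel.

    The page count must equal the panel size. If the file embeds channel
    names they are cross-checked against the panel (mismatch warns, panel
    order wins).
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(panel):
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but the panel defines {len(panel)} channels"
        )
    names = meta.get("channel_names") if isinstance(meta, dict) else None
    if names and list(names) != panel.markers:
        warnings.warn(
            f"{path}: embedded channel names differ from the panel; using panel order"
        )
    px = float(meta.get("pixel_size_um", pixel_size_um)) if isinstance(meta, dict) else pixel_size_um
    data = np.moveaxis(arr.astype(float), 0, 2)
    return MultiChannelImage(data, panel.markers, px)


def write_label_mask(mask: LabelMask, path) -> None:
    """Label mask as a 16-bit single-page TIFF."""
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 cells; cannot store as 16-bit mask")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


def read_label_mask(path, roi_id: str = "") -> LabelMask:
    return LabelMask(tifffile.imread(path).astype(int), roi_id)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
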