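"""Pixel-level preparation of raw IMC regions of interest.

Imaging mass cytometry records one image plane per metal-tagged antibody.
Before any single-cell quantification three corrections are applied, in
order: channel-spillover compensation (isotope impurity and oxide signal
leaks a few percent of one channel into its mass neighbours), 3x3 median
filtering against shot-noise speckle, and an optional percentile contrast
rescale to 0-255 used only for visualisation and mask thresholding.

Per-cell expression statistics are always computed on compensated,
median-filtered intensities, never on the rescaled image, so that the
contrast step cannot distort expression comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MultiChannelImage",
    "SpilloverMatrix",
    "compensate_spillover",
    "denoise_median",
    "rescale_contrast",
]


@dataclass
class MultiChannelImage:
    """H x W x C stack of nonnegative marker intensities.

    Parameters
    ----------
    data
        Array of shape (H, W, C), float, no NaN, nonnegative.
    channel_names
        Marker label per channel, length C.
    pixel_size_um
        Physical edge length of one pixel in micrometres (IMC ablates
        at 1 um resolution, the default).
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected (H, W, C) array, got shape {self.data.shape}")
        if self.data.shape[2] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[2]} planes but {len(self.channel_names)} channel names"
            )
        if np.isnan(self.data).any():
            raise ValueError("image contains NaN")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D plane for a marker by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.data[:, :, idx]

    def with_data(self, data: np.ndarray) -> "MultiChannelImage":
        return MultiChannelImage(data, list(self.channel_names), self.pixel_size_um)


@dataclass
class SpilloverMatrix:
    """Channel crosstalk matrix, rows = source channel, columns = receiver.

    The observed pixel vector is modelled as ``observed = true @ S``; the
    diagonal is exactly 1 and off-diagonal entries are the fraction of a
    source channel's signal that leaks into each receiving channel.
    """

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        C = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != C:
            raise ValueError(f"spillover matrix must be square, got {self.values.shape}")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("spillover diagonal must be exactly 1")
        off = self.values[~np.eye(C, dtype=bool)]
        if (off < 0).any() or (off >= 1).any():
            raise ValueError("off-diagonal spillover must lie in [0, 1)")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(C)]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @classmethod
    def identity(cls, channel_names: list[str]) -> "SpilloverMatrix":
        return cls(np.eye(len(channel_names)), list(channel_names))


def compensate_spillover(img: MultiChannelImage, S: SpilloverMatrix) -> MultiChannelImage:
    """Invert channel crosstalk per pixel.

    Solves ``observed = true @ S`` for the true channel vector at every
    pixel and clips negative solutions to zero (metal counts cannot be
    negative; small negatives arise where the observed signal sits below
    the leaked-in fraction).

    Raises
    ------
    ValueError
        If the matrix dimension does not match the image, or S is singular.
    """
    if S.n_channels != img.n_channels:
        raise ValueError(
            f"spillover matrix has {S.n_channels} channels, image has {img.n_channels}"
        )
    H, W, C = img.data.shape
    obs = img.data.reshape(-1, C)
    try:
        # observed = true @ S  <=>  S.T @ true.T = observed.T
        true = np.linalg.solve(S.values.T, obs.T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"spillover matrix is singular and cannot be inverted: {exc}") from exc
    np.clip(true, 0.0, None, out=true)
    return img.with_data(true.reshape(H, W, C))


def denoise_median(img: MultiChannelImage, size: int = 3) -> MultiChannelImage:
    """Per-channel square median filter (default 3x3), edges replicated."""
    out = np.empty_like(img.data)
    for c in range(img.n_channels):
        ndimage.median_filter(img.data[:, :, c], size=size, mode="nearest", output=out[:, :, c])
    return img.with_data(out)


def rescale_contrast(
    img: MultiChannelImage, low_pct: float = 1.0, high_pct: float = 99.0
) -> MultiChannelImage:
    """Linearly redistribute each channel onto the 0-255 range.

    The ``low_pct`` percentile maps to 0 and the ``high_pct`` percentile to
    255; values outside are clipped. A channel whose two percentiles
    coincide (e.g. a constant or empty channel) maps to all zeros.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    out = np.empty_like(img.data)
    for c in range(img.n_channels):
        plane = img.data[:, :, c]
        lo, hi = np.percentile(plane, [low_pct, high_pct])
        if hi <= lo:
            out[:, :, c] = 0.0
        else:
            out[:, :, c] = np.clip((plane - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    return img.with_data(out)
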