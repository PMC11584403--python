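"""Immunofluorescence and multiplex-imaging quantifications.

Three defined measurements:

- masked mean intensity: images are standardised to their first 1,250
  lines; a mask is thresholded at half the sample mean of a reference
  channel (E-cadherin for the MELK quantification) and the target
  channel's mean intensity over mask pixels is reported;
- epithelial region masks: per-channel thresholds (set manually per
  image) are unioned into a consensus mask, smoothed with a Gaussian
  filter (sigma 2.0), re-binarised, hole-filled and labelled into
  connected regions (8-connectivity);
- positive-cell fractions: per epithelial region, the fraction of
  segmented cells positive for a marker; per sample, the unweighted mean
  over its regions.

Pixels equal to a threshold count as positive (deterministic boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian

__all__ = [
    "ChannelImage",
    "masked_mean_intensity",
    "epithelial_region_mask",
    "positive_cell_fraction",
]


@dataclass
class ChannelImage:
    """Named 2-D intensity channels sharing one shape."""

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if (np.asarray(ch) < 0).any():
                raise ValueError(f"channel {name!r} has negative intensities")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def to_tiff(self, path) -> None:
        import tifffile

        names = sorted(self.channels)
        stack = np.stack([self.channels[n] for n in names]).astype(np.float32)
        tifffile.imwrite(
            path,
            stack,
            photometric="minisblack",
            planarconfig="separate",
            metadata={"channels": names},
        )

    @classmethod
    def from_tiff(cls, path, channel_names: list[str] | None = None) -> "ChannelImage":
        import json

        import tifffile

        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            names = channel_names
            if names is None and tif.shaped_metadata:
                names = tif.shaped_metadata[0].get("channels")
            if names is None and tif.imagej_metadata:
                raw = tif.imagej_metadata.get("channels")
                names = json.loads(raw) if isinstance(raw, str) else raw
        if names is None:
            names = [f"channel_{i}" for i in range(stack.shape[0])]
        return cls(channels={n: stack[i] for i, n in enumerate(names)})


def masked_mean_intensity(
    img: ChannelImage,
    mask_channel: str,
    target_channel: str,
    line_limit: int = 1250,
) -> float:
    """Mean target intensity over the half-mean mask of a reference channel.

    Both channels are cropped to the first ``line_limit`` rows; the mask
    threshold is half the cropped mask channel's mean; mask pixels are
    those >= threshold. Returns NaN with a warning if the mask is empty.
    """
    mask_img = np.asarray(img[mask_channel], dtype=float)[:line_limit]
    target_img = np.asarray(img[target_channel], dtype=float)[:line_limit]
    threshold = 0.5 * mask_img.mean()
    mask = mask_img >= threshold
    if not mask.any():
        warnings.warn(
            f"empty {mask_channel!r} mask: no pixel reaches half the sample mean",
            stacklevel=2,
        )
        return float("nan")
    return float(target_img[mask].mean())


def epithelial_region_mask(
    img: ChannelImage,
    thresholds: dict[str, float],
    sigma: float = 2.0,
) -> np.ndarray:
    """Consensus epithelial region mask, labelled into connected regions.

    Each channel named in ``thresholds`` is binarised at its (manually
    set) threshold; the binary masks are unioned, Gaussian-smoothed
    (``sigma``), re-binarised at 0.5, hole-filled, and labelled with
    8-connectivity. Returns an integer label image (0 = background).
    """
    if not thresholds:
        raise ValueError("at least one channel threshold required")
    consensus = np.zeros(img.shape, dtype=bool)
    for name, thr in thresholds.items():
        consensus |= np.asarray(img[name], dtype=float) >= thr
    smoothed = gaussian(consensus.astype(float), sigma=sigma, preserve_range=True)
    binary = smoothed >= 0.5
    filled = ndimage.binary_fill_holes(binary)
    return measure.label(filled, connectivity=2)


def positive_cell_fraction(
    cells: pd.DataFrame, marker: str
) -> tuple[pd.Series, pd.Series]:
    """Positive-cell fraction per region and its unweighted sample mean.

    ``cells`` has one row per segmented cell with columns ``sample``,
    ``region`` and a boolean positivity column named by ``marker``.
    Returns ``(per_region, per_sample)``; ``per_region`` is indexed by
    (sample, region). Regions with zero cells cannot appear in a row-wise
    table; an empty sample raises through the groupby being absent.
    """
    for col in ("sample", "region", marker):
        if col not in cells.columns:
            raise ValueError(f"cell table missing column {col!r}")
    flags = cells[marker].astype(bool)
    per_region = flags.groupby([cells["sample"], cells["region"]]).mean()
    per_sample = per_region.groupby(level="sample").mean()
    return per_region, per_sample
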