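"""Duct-like synthetic multichannel images with truth masks.

Images carry at least four channels named after the study's stains
(E-cadherin, MELK, pan-CK, SMA). Epithelial ducts are rings (annuli):
E-cadherin and pan-CK are high on the ring, SMA traces a thin outer
myoepithelial rim, and MELK intensity inside the ring is configurable so
the masked quantification can be tested against a planted constant.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk

from bclineage.imaging import ChannelImage

__all__ = ["generate_image", "default_duct_geometry"]

DEFAULT_CHANNEL_MEANS = {
    "E-cadherin": 200.0,
    "MELK": 80.0,
    "pan-CK": 180.0,
    "SMA": 120.0,
}


def default_duct_geometry(
    shape: tuple[int, int], n_ducts: int, seed: int
) -> list[tuple[int, int, int, int]]:
    """Random non-touching ducts as (row, col, outer_radius, inner_radius)."""
    rng = np.random.default_rng(seed)
    hi = max(12, min(60, min(shape) // 5))
    lo = max(8, hi // 2)
    ducts = []
    attempts = 0
    while len(ducts) < n_ducts and attempts < 500:
        attempts += 1
        r_out = int(rng.integers(lo, hi))
        r_in = int(r_out * rng.uniform(0.4, 0.6))
        row = int(rng.integers(r_out + 5, shape[0] - r_out - 5))
        col = int(rng.integers(r_out + 5, shape[1] - r_out - 5))
        if all(
            (row - r0) ** 2 + (col - c0) ** 2 > (r_out + ro0 + 10) ** 2
            for r0, c0, ro0, _ in ducts
        ):
            ducts.append((row, col, r_out, r_in))
    return ducts


def generate_image(
    shape: tuple[int, int] = (300, 300),
    duct_geometry: list[tuple[int, int, int, int]] | None = None,
    channel_means: dict[str, float] | None = None,
    seed: int = 0,
    *,
    background: float = 10.0,
    noise_sd: float = 2.0,
) -> tuple[ChannelImage, dict[str, np.ndarray]]:
    """Generate a duct-like multichannel image plus truth masks.

    Returns ``(image, masks)`` with masks ``"epithelium"`` (the duct
    rings, where E-cadherin/pan-CK/MELK signal lives) and ``"sma_rim"``
    (a thin outer rim). Channel intensities are the stated means on their
    mask plus Gaussian noise clipped at zero.
    """
    rng = np.random.default_rng(seed)
    means = {**DEFAULT_CHANNEL_MEANS, **(channel_means or {})}
    if duct_geometry is None:
        duct_geometry = default_duct_geometry(shape, n_ducts=3, seed=seed)

    ring = np.zeros(shape, dtype=bool)
    rim = np.zeros(shape, dtype=bool)
    for row, col, r_out, r_in in duct_geometry:
        outer = np.zeros(shape, dtype=bool)
        inner = np.zeros(shape, dtype=bool)
        rr, cc = disk((row, col), r_out, shape=shape)
        outer[rr, cc] = True
        rr, cc = disk((row, col), r_in, shape=shape)
        inner[rr, cc] = True
        ring |= outer & ~inner
        rr, cc = disk((row, col), min(r_out + 4, min(shape) // 2), shape=shape)
        rim_disk = np.zeros(shape, dtype=bool)
        rim_disk[rr, cc] = True
        rim |= rim_disk & ~outer

    channels: dict[str, np.ndarray] = {}
    for name in ("E-cadherin", "pan-CK", "MELK"):
        img = np.full(shape, background, dtype=float)
        img[ring] = means[name]
        img += rng.normal(0.0, noise_sd, size=shape)
        channels[name] = np.clip(img, 0.0, None)
    sma = np.full(shape, background, dtype=float)
    sma[rim] = means["SMA"]
    sma += rng.normal(0.0, noise_sd, size=shape)
    channels["SMA"] = np.clip(sma, 0.0, None)

    return ChannelImage(channels=channels), {"epithelium": ring, "sma_rim": rim}
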