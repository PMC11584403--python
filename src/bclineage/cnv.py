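"""Overlap-weighted mapping of copy-ratio segments to genes and arms.

For a target interval (gene or chromosome arm) overlapped by one or more
denoised copy-ratio segments, the weighted ratio is

    w = sum_i(ratio_i * overlap_i) / sum_i(overlap_i)

over the overlapping segments, with overlap measured in bases. The call
is amplified when w exceeds the upper bound, deleted when w falls below
the lower bound, neutral otherwise; the default neutral zone (0.9, 1.1)
mirrors the upstream segment caller's thresholds, and boundary values
are neutral (strict inequalities). Targets with no overlapping segment
are "no-call".

Averaging happens in linear copy-ratio space by default (the 0.9/1.1
thresholds are linear); log2-space averaging is available by flag.
Sample-adaptive bounds derived from the dispersion of segment ratios can
be enabled; they are clamped so the neutral zone is never narrower than
the (0.9, 1.1) envelope.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["CopySegment", "GeneInterval", "adaptive_bounds", "weighted_interval_call"]

DEFAULT_BOUNDS = (0.9, 1.1)


@dataclass(frozen=True)
class CopySegment:
    """A denoised copy-ratio segment (0-based half-open, linear ratio)."""

    chrom: str
    start: int
    end: int
    copy_ratio: float
    call: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("empty segment interval")
        if self.copy_ratio <= 0:
            raise ValueError("copy ratio must be positive")


@dataclass(frozen=True)
class GeneInterval:
    """A gene or chromosome-arm target interval (0-based half-open)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("empty target interval")


def adaptive_bounds(
    segments: list[CopySegment],
    z: float = 2.0,
    envelope: tuple[float, float] = DEFAULT_BOUNDS,
) -> tuple[float, float]:
    """Sample-adaptive neutral-zone bounds 1 +/- z*sigma of segment ratios,
    clamped so the neutral zone is never narrower than ``envelope``."""
    sigma = float(np.std([s.copy_ratio for s in segments])) if segments else 0.0
    lower, upper = 1.0 - z * sigma, 1.0 + z * sigma
    return (min(lower, envelope[0]), max(upper, envelope[1]))


def weighted_interval_call(
    segments: list[CopySegment],
    targets: list[GeneInterval],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    *,
    log_space: bool = False,
) -> pd.DataFrame:
    """Per-target weighted copy ratio and {amplified, neutral, deleted} call.

    Returns a DataFrame indexed by target name with columns ``weighted_ratio``
    and ``call`` (``"no-call"`` with NaN ratio for targets with no
    overlapping segment).
    """
    lower, upper = bounds
    if not (lower < 1 < upper):
        raise ValueError("bounds must satisfy lower < 1 < upper")

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for seg in segments:
        trees[seg.chrom].addi(seg.start, seg.end, seg.copy_ratio)

    rows = []
    for t in targets:
        hits = trees[t.chrom].overlap(t.start, t.end)
        total = 0
        acc = 0.0
        for iv in hits:
            overlap = min(iv.end, t.end) - max(iv.begin, t.start)
            assert overlap > 0
            value = np.log2(iv.data) if log_space else iv.data
            acc += value * overlap
            total += overlap
        if total == 0:
            rows.append({"target": t.name, "weighted_ratio": np.nan, "call": "no-call"})
            continue
        w = acc / total
        if log_space:
            w = float(2.0**w)
        call = "amplified" if w > upper else ("deleted" if w < lower else "neutral")
        rows.append({"target": t.name, "weighted_ratio": w, "call": call})
    return pd.DataFrame(rows).set_index("target")
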