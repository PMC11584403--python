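"""Per-sample synthetic peak sets emulating MACS2-style calls.

Peaks have random summits, widths uniform on 200-1500 bp, and -log10
q-value scores drawn log-uniform. A configurable fraction of peaks is
deliberately placed overlapping an earlier peak so that the iterative
removal procedure has work to do; a fraction is placed on chrY and over
planted N-gap intervals so the standardisation filters are exercised.
N-gaps are represented as interval lists (the peak filter needs only
intervals, never sequence).
"""

from __future__ import annotations

import numpy as np

from bclineage.peaks import Peak

__all__ = ["generate_peak_sets", "generate_n_gaps"]


def generate_n_gaps(
    genome_lengths: dict[str, int], seed: int, gaps_per_chrom: int = 2, gap_width: int = 5000
) -> dict[str, list[tuple[int, int]]]:
    """Planted N-gap intervals per chromosome (0-based half-open)."""
    rng = np.random.default_rng(seed)
    gaps: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in genome_lengths.items():
        if length <= 2 * gap_width:
            continue
        starts = rng.integers(0, length - gap_width, size=gaps_per_chrom)
        gaps[chrom] = sorted((int(s), int(s) + gap_width) for s in starts)
    return gaps


def _random_peak(
    rng: np.random.Generator, chrom: str, length: int, sample: str,
    anchor: Peak | None = None,
) -> Peak:
    width = int(rng.integers(200, 1501))
    if anchor is not None:
        # overlap the anchor by at least one base
        lo = max(0, anchor.start - width + 1)
        hi = min(length - width, anchor.end - 1)
        start = int(rng.integers(lo, max(lo + 1, hi)))
    else:
        start = int(rng.integers(0, max(1, length - width)))
    end = start + width
    summit = int(rng.integers(start, end))
    score = float(np.exp(rng.uniform(np.log(2.0), np.log(500.0))))
    return Peak(chrom=chrom, start=start, end=end, summit=summit, score=score, sample=sample)


def generate_peak_sets(
    n_samples: int,
    peaks_per_sample: int,
    genome_lengths: dict[str, int],
    seed: int,
    *,
    overlap_fraction: float = 0.3,
    chry_fraction: float = 0.05,
    ngap_fraction: float = 0.05,
    n_gaps: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[dict[str, list[Peak]], dict[str, list[tuple[int, int]]]]:
    """Generate per-sample peak lists plus the N-gap interval list.

    ``chry_fraction`` of peaks land on chrY (when present in
    ``genome_lengths``) and ``ngap_fraction`` are centred inside a planted
    N-gap; both should be removed by standardisation.
    """
    rng = np.random.default_rng(seed)
    if n_gaps is None:
        n_gaps = generate_n_gaps(
            {c: l for c, l in genome_lengths.items() if c not in ("chrY", "Y")}, seed
        )
    autosomes = [c for c in genome_lengths if c not in ("chrY", "Y")]
    has_y = "chrY" in genome_lengths or "Y" in genome_lengths
    y_name = "chrY" if "chrY" in genome_lengths else "Y"

    out: dict[str, list[Peak]] = {}
    for s_idx in range(n_samples):
        sample = f"S{s_idx + 1:03d}"
        peaks: list[Peak] = []
        while len(peaks) < peaks_per_sample:
            u = rng.random()
            if has_y and u < chry_fraction:
                peaks.append(_random_peak(rng, y_name, genome_lengths[y_name], sample))
            elif u < chry_fraction + ngap_fraction and n_gaps:
                chrom = autosomes[int(rng.integers(len(autosomes)))]
                gaps = n_gaps.get(chrom)
                if not gaps:
                    continue
                gs, ge = gaps[int(rng.integers(len(gaps)))]
                width = int(rng.integers(200, 1501))
                start = int(rng.integers(gs, ge))
                end = min(start + width, genome_lengths[chrom])
                summit = int(rng.integers(start, end))
                score = float(np.exp(rng.uniform(np.log(2.0), np.log(500.0))))
                peaks.append(Peak(chrom, start, end, summit, score, sample))
            elif peaks and rng.random() < overlap_fraction:
                anchor = peaks[int(rng.integers(len(peaks)))]
                if anchor.chrom == y_name:
                    continue
                peaks.append(
                    _random_peak(rng, anchor.chrom, genome_lengths[anchor.chrom], sample, anchor)
                )
            else:
                chrom = autosomes[int(rng.integers(len(autosomes)))]
                peaks.append(_random_peak(rng, chrom, genome_lengths[chrom], sample))
        out[sample] = peaks
    return out, n_gaps
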