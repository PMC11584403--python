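"""snATAC peak standardisation, merging and promoter annotation.

Per-sample MACS2-style peak calls are standardised (chrY and N-gap peaks
dropped, every peak resized to a fixed 501 bp window centred on its
summit) and reduced to a non-overlapping set by iterative overlap
removal: the most significant remaining peak is retained and every peak
directly overlapping it is deleted, until none remain. For the cohort
atlas, per-sample significance scores (-log10 q) are first normalised to
a score per million so they are comparable across samples, then the
pooled peaks undergo the same iterative removal ranked by SPM.

Peak coordinates are 0-based half-open; a summit is an absolute genomic
position inside its peak.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from collections import defaultdict
from dataclasses import dataclass, replace

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Peak",
    "PEAK_WIDTH",
    "standardize_peaks",
    "iterative_overlap_removal",
    "score_per_million",
    "build_cohort_peakset",
    "annotate_peak_promoters",
    "read_peaks_bed",
    "write_peaks_bed",
]

PEAK_WIDTH = 501
_HALF = PEAK_WIDTH // 2  # 250


@dataclass(frozen=True)
class Peak:
    """A peak interval with its summit and significance score.

    ``score`` is the -log10 q-value from peak calling; ``spm`` is the
    score-per-million normalised value (unset until normalisation).
    """

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    sample: str = ""
    spm: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty peak interval {self.chrom}:{self.start}-{self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak {self.chrom}:{self.start}-{self.end}"
            )
        if self.score < 0:
            raise ValueError("peak score must be nonnegative")

    @property
    def width(self) -> int:
        return self.end - self.start


def standardize_peaks(
    peaks: list[Peak],
    genome_lengths: dict[str, int],
    n_gaps: dict[str, list[tuple[int, int]]] | None = None,
    *,
    drop_chroms: tuple[str, ...] = ("chrY", "Y"),
) -> list[Peak]:
    """Drop chrY / N-gap peaks and resize the rest to 501 bp at the summit.

    The resized window is [summit-250, summit+251); peaks whose window
    would extend past the chromosome bounds are dropped (clipping would
    break the fixed-width invariant).
    """
    gap_trees: dict[str, IntervalTree] = {}
    for chrom, ivals in (n_gaps or {}).items():
        gap_trees[chrom] = IntervalTree.from_tuples((s, e) for s, e in ivals if e > s)

    out = []
    for p in peaks:
        if p.chrom in drop_chroms:
            continue
        tree = gap_trees.get(p.chrom)
        if tree is not None and tree.overlap(p.start, p.end):
            continue
        start, end = p.summit - _HALF, p.summit + _HALF + 1
        length = genome_lengths.get(p.chrom)
        if length is None:
            raise ValueError(f"no genome length for chromosome {p.chrom!r}")
        if start < 0 or end > length:
            continue
        out.append(replace(p, start=start, end=end))
    return out


def iterative_overlap_removal(peaks: list[Peak], by: str = "score") -> list[Peak]:
    """Greedy reduction to a non-overlapping peak set.

    Repeatedly retains the highest-ranked remaining peak (by ``by``,
    either ``"score"`` or ``"spm"``; ties broken by (chrom, start)) and
    deletes every remaining peak sharing at least one base with it. This
    is equivalent to a single pass in rank order keeping each peak iff it
    overlaps no already-kept peak. Returned in genomic order.
    """
    def rank(p: Peak):
        value = p.spm if by == "spm" else p.score
        if value is None:
            raise ValueError(f"peak has no {by!r} value set")
        return (-value, p.chrom, p.start, p.end, p.sample)

    kept: list[Peak] = []
    kept_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for p in sorted(peaks, key=rank):
        starts = kept_by_chrom[p.chrom]
        # find any kept interval overlapping [p.start, p.end)
        i = bisect_left(starts, (p.start, p.start))
        overlaps = False
        if i < len(starts) and starts[i][0] < p.end:
            overlaps = True
        if i > 0 and starts[i - 1][1] > p.start:
            overlaps = True
        if not overlaps:
            insort(starts, (p.start, p.end))
            kept.append(p)
    kept.sort(key=lambda p: (p.chrom, p.start, p.end))
    _assert_non_overlapping(kept)
    return kept


def _assert_non_overlapping(peaks: list[Peak]) -> None:
    prev: Peak | None = None
    for p in peaks:
        if prev is not None and prev.chrom == p.chrom and p.start < prev.end:
            raise AssertionError("overlap removal produced overlapping peaks")
        prev = p


def score_per_million(peaks: list[Peak]) -> list[Peak]:
    """Normalise peak scores within each sample to a score per million.

    spm_i = score_i / sum_j score_j * 1e6, the sum running over the peak's
    sample. A sample whose scores sum to zero is degenerate and rejected.
    """
    totals: dict[str, float] = defaultdict(float)
    for p in peaks:
        totals[p.sample] += p.score
    for sample, total in totals.items():
        if total == 0:
            raise ValueError(f"sample {sample!r} has all-zero peak scores")
    return [replace(p, spm=p.score / totals[p.sample] * 1e6) for p in peaks]


def build_cohort_peakset(per_sample_peaks: dict[str, list[Peak]]) -> list[Peak]:
    """Merge standardized, SPM-normalised sample peak sets into one atlas.

    All samples' peaks are pooled and reduced by iterative overlap removal
    ranked on SPM; each retained peak carries its winning sample of origin
    in ``sample``.
    """
    pooled: list[Peak] = []
    for sample, plist in per_sample_peaks.items():
        for p in plist:
            if p.spm is None:
                raise ValueError(
                    f"peak in sample {sample!r} lacks SPM; run score_per_million first"
                )
            pooled.append(replace(p, sample=p.sample or sample))
    return iterative_overlap_removal(pooled, by="spm")


def annotate_peak_promoters(
    peaks: list[Peak],
    tss: pd.DataFrame,
    *,
    upstream: int = 1000,
    downstream: int = 100,
) -> pd.DataFrame:
    """Label each peak promoter/distal against strand-oriented TSS windows.

    ``tss`` has columns gene, chrom, tss (0-based position), strand. The
    promoter window spans ``upstream`` bases upstream to ``downstream``
    bases downstream of the TSS, oriented by gene strand. A peak
    overlapping at least one window is a promoter peak; every gene hit is
    reported (comma-joined).
    """
    if not set(tss["strand"].unique()) <= {"+", "-"}:
        raise ValueError("TSS strand must be '+' or '-'")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for row in tss.itertuples(index=False):
        if row.strand == "+":
            lo, hi = row.tss - upstream, row.tss + downstream + 1
        else:
            lo, hi = row.tss - downstream, row.tss + upstream + 1
        trees[row.chrom].addi(lo, hi, row.gene)

    rows = []
    for p in peaks:
        hits = sorted({iv.data for iv in trees[p.chrom].overlap(p.start, p.end)})
        rows.append(
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "annotation": "promoter" if hits else "distal",
                "genes": ",".join(hits),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BED6+2 I/O: chrom, start, end, name, score, strand, summit, sample

def write_peaks_bed(peaks: list[Peak], path) -> None:
    rows = [
        {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "name": f"{p.chrom}:{p.start}-{p.end}",
            "score": p.score,
            "strand": ".",
            "summit": p.summit,
            "sample": p.sample,
        }
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False, float_format="%.17g")


def read_peaks_bed(path) -> list[Peak]:
    cols = ["chrom", "start", "end", "name", "score", "strand", "summit", "sample"]
    table = pd.read_csv(path, sep="\t", header=None, names=cols, float_precision="round_trip")
    return [
        Peak(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            summit=int(r.summit),
            score=float(r.score),
            sample="" if pd.isna(r.sample) else str(r.sample),
        )
        for r in table.itertuples(index=False)
    ]
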