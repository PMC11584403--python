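"""Per-cell and per-nucleus quality-control filters.

RNA barcodes are removed when any metric falls on the *removal* side of
its printed bound, with strict inequalities exactly as printed: a cell
with total transcript counts <300 is removed, so 300 is kept; genes
detected <200 or >10,000 removes, so both 200 and 10,000 are kept.

ATAC nuclei are kept only when every metric satisfies its printed *keep*
condition, again strictly: fragments in peaks must be >1,000 and <20,000,
so 1,000 and 20,000 both fail; percentage of reads in peaks must be >15,
so exactly 15 fails.

All filters operate row-wise on a :class:`pandas.DataFrame` and return a
boolean keep mask plus per-criterion removal counts so that a QC report
can state which filter removed how many barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RnaQcThresholds",
    "AtacQcThresholds",
    "QcResult",
    "rna_cell_qc",
    "atac_nucleus_qc",
]

RNA_METRICS = ("total_counts", "genes_detected", "umis", "pct_mito")
ATAC_METRICS = (
    "fragments_in_peaks",
    "pct_reads_in_peaks",
    "blacklist_fraction",
    "nucleosome_signal",
    "tss_enrichment",
)


@dataclass(frozen=True)
class RnaQcThresholds:
    """Removal bounds for RNA barcodes (strict inequalities).

    A cell is removed iff total_counts < min_total_counts, or
    genes_detected < min_genes / > max_genes, or umis < min_umis /
    > max_umis, or pct_mito > max_pct_mito.
    """

    min_total_counts: float = 300
    min_genes: float = 200
    max_genes: float = 10_000
    min_umis: float = 1_000
    max_umis: float = 10_000
    max_pct_mito: float = 10.0


@dataclass(frozen=True)
class AtacQcThresholds:
    """Keep bounds for ATAC nuclei (strict inequalities).

    A nucleus is kept iff min_fragments < fragments_in_peaks <
    max_fragments, pct_reads_in_peaks > min_pct_reads_in_peaks,
    blacklist_fraction < max_blacklist_fraction, nucleosome_signal <
    max_nucleosome_signal and tss_enrichment > min_tss_enrichment.
    """

    min_fragments: float = 1_000
    max_fragments: float = 20_000
    min_pct_reads_in_peaks: float = 15.0
    max_blacklist_fraction: float = 0.05
    max_nucleosome_signal: float = 10.0
    min_tss_enrichment: float = 2.0


@dataclass
class QcResult:
    """Keep mask plus an audit of how many barcodes each criterion removed."""

    keep: pd.Series
    removed_by: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())


def _require_columns(table: pd.DataFrame, columns: tuple[str, ...]) -> None:
    for col in columns:
        if col not in table.columns:
            raise ValueError(f"QC table is missing required metric column {col!r}")
        bad = table[col].isna()
        if bad.any():
            barcode = table.index[bad][0]
            raise ValueError(f"barcode {barcode!r} has missing metric {col!r}")


def rna_cell_qc(
    cells: pd.DataFrame, thresholds: RnaQcThresholds | None = None
) -> QcResult:
    """Apply the RNA barcode filters; keep iff every criterion passes.

    Parameters
    ----------
    cells
        One row per barcode; columns ``total_counts``, ``genes_detected``,
        ``umis``, ``pct_mito`` (percent, 0-100). The index is the barcode.
    thresholds
        Bounds; defaults to the study values.
    """
    t = thresholds or RnaQcThresholds()
    _require_columns(cells, RNA_METRICS)

    criteria = {
        "low_total_counts": cells["total_counts"] >= t.min_total_counts,
        "low_genes": cells["genes_detected"] >= t.min_genes,
        "high_genes": cells["genes_detected"] <= t.max_genes,
        "low_umis": cells["umis"] >= t.min_umis,
        "high_umis": cells["umis"] <= t.max_umis,
        "high_pct_mito": cells["pct_mito"] <= t.max_pct_mito,
    }
    return _combine(criteria, cells.index)


def atac_nucleus_qc(
    nuclei: pd.DataFrame, thresholds: AtacQcThresholds | None = None
) -> QcResult:
    """Apply the ATAC nucleus filters; keep iff every criterion passes.

    ``nuclei`` has one row per barcode with columns ``fragments_in_peaks``,
    ``pct_reads_in_peaks`` (percent), ``blacklist_fraction`` (fraction),
    ``nucleosome_signal`` and ``tss_enrichment``.
    """
    t = thresholds or AtacQcThresholds()
    _require_columns(nuclei, ATAC_METRICS)

    criteria = {
        "low_fragments": nuclei["fragments_in_peaks"] > t.min_fragments,
        "high_fragments": nuclei["fragments_in_peaks"] < t.max_fragments,
        "low_pct_reads_in_peaks": nuclei["pct_reads_in_peaks"]
        > t.min_pct_reads_in_peaks,
        "high_blacklist": nuclei["blacklist_fraction"] < t.max_blacklist_fraction,
        "high_nucleosome": nuclei["nucleosome_signal"] < t.max_nucleosome_signal,
        "low_tss_enrichment": nuclei["tss_enrichment"] > t.min_tss_enrichment,
    }
    return _combine(criteria, nuclei.index)


def _combine(criteria: dict[str, pd.Series], index: pd.Index) -> QcResult:
    keep = pd.Series(np.ones(len(index), dtype=bool), index=index)
    removed_by: dict[str, int] = {}
    for name, passed in criteria.items():
        passed = passed.astype(bool)
        removed_by[name] = int((~passed).sum())
        keep &= passed
    return QcResult(keep=keep, removed_by=removed_by)
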