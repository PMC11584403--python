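"""Multi-caller variant consensus filtering, pathogenicity tiers and LOH.

Somatic, tumor-only and germline call sets are merged and filtered with
pure, auditable predicates: every clause of each filter is evaluated
independently so the audit trail records exactly why a variant survived
or fell.

Variant identity is the tuple (chrom, pos, ref, alt) after parsimony
trimming (shared allele suffix then prefix removed, position adjusted),
which canonicalises the representation differences between callers that
do not require reference-sequence context.

Coordinates in variant records are 1-based inclusive (VCF convention);
interval files are 0-based half-open (BED convention). Conversions happen
at the interval-membership boundary only.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VariantRecord",
    "ConsensusVariant",
    "CellAlleleCount",
    "RescueResult",
    "trim_alleles",
    "merge_somatic_calls",
    "filter_tumor_only",
    "rescue_variants",
    "merge_germline_calls",
    "classify_pathogenicity",
    "loh_fisher",
    "count_cell_alleles",
    "map_variants_to_cells",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_vcf_calls",
]

SOMATIC_CALLERS = frozenset({"strelka", "varscan", "mutect", "pindel"})
SOMATIC_SNV_CALLERS = frozenset({"strelka", "varscan", "mutect"})
SOMATIC_INDEL_CALLERS = frozenset({"strelka", "varscan", "pindel"})
GERMLINE_CALLERS = frozenset({"gatk", "varscan", "pindel"})

PATHOGENIC_TIERS = ("pathogenic", "likely_pathogenic", "prioritized_VUS", "none")


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim an allele pair: drop shared suffix, then shared prefix.

    The position (1-based) advances by one for every shared leading base
    removed. At least one base is always retained on each allele.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class VariantRecord:
    """One candidate variant from one caller (or one consensus record).

    Depth/alt counts refer to the tumor and matched normal samples;
    annotation flags (exonic, dbSNP, COSMIC, gnomAD AF, ClinVar, CharGer)
    are inputs from upstream annotation, not recomputed here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    caller: str
    tumor_depth: int = 0
    tumor_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    exonic: bool = False
    in_dbsnp: bool = False
    in_cosmic: bool = False
    gnomad_af: float | None = None
    clinvar: str = "none"
    charger_score: float | None = None
    sample: str | None = None
    rescued: bool = False

    def __post_init__(self) -> None:
        if self.tumor_alt > self.tumor_depth or self.normal_alt > self.normal_depth:
            raise ValueError(
                f"alt count exceeds depth at {self.chrom}:{self.pos} {self.ref}>{self.alt}"
            )
        self.pos, self.ref, self.alt = trim_alleles(self.pos, self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth > 0 else math.nan

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth > 0 else math.nan


@dataclass
class ConsensusVariant:
    """A merged variant with its supporting-caller set and filter audit."""

    record: VariantRecord
    callers: frozenset[str]
    filters: dict[str, bool] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.record.key

    @property
    def passed(self) -> bool:
        return all(self.filters.values())


@dataclass
class CellAlleleCount:
    """Unique-molecule ref/alt support for one variant in one cell."""

    barcode: str
    variant_key: tuple[str, int, str, str]
    ref_reads: int
    alt_reads: int


@dataclass
class RescueResult:
    calls: list[VariantRecord]
    unassessable: list[tuple[str, tuple[str, int, str, str]]]


def _group_by_key(calls: list[VariantRecord]) -> dict[tuple, list[VariantRecord]]:
    groups: dict[tuple, list[VariantRecord]] = defaultdict(list)
    seen_ref: dict[tuple[str, int, str], str] = {}
    for rec in calls:
        ident = (rec.chrom, rec.pos, rec.alt)
        if ident in seen_ref and seen_ref[ident] != rec.ref:
            raise ValueError(
                f"inconsistent ref allele at {rec.chrom}:{rec.pos} alt {rec.alt}: "
                f"{seen_ref[ident]!r} vs {rec.ref!r}"
            )
        seen_ref[ident] = rec.ref
        groups[rec.key].append(rec)
    return groups


def _representative(records: list[VariantRecord]) -> VariantRecord:
    """Deterministic counts for a merged record: the supporter with the
    highest tumor depth (ties broken by caller id)."""
    return max(records, key=lambda r: (r.tumor_depth, r.caller))


def merge_somatic_calls(
    calls: list[VariantRecord],
    *,
    max_normal_vaf: float = 0.02,
    min_tumor_vaf: float = 0.05,
    min_tumor_depth: int = 14,
    min_normal_depth: int = 8,
    max_indel_length: int = 100,
    min_callers: int = 2,
    return_audit: bool = False,
):
    """Merge tumor/normal somatic calls from up to four callers.

    A variant (keyed chrom:pos:ref:alt) is kept iff it is supported by at
    least two admissible callers (SNVs: strelka/varscan/mutect; indels:
    strelka/varscan/pindel), normal VAF <= 0.02 and tumor VAF >= 0.05,
    tumor depth >= 14 and normal depth >= 8, indel length < 100 bp, it is
    exonic, and it is not in dbSNP unless also in COSMIC. Counts and flags
    of the merged record come from the supporting caller with the highest
    tumor depth.

    Returns the list of passing :class:`ConsensusVariant`; with
    ``return_audit=True`` returns ``(kept, audit)`` where ``audit`` is a
    DataFrame with one row per candidate and one boolean column per clause.
    """
    unknown = {r.caller for r in calls} - SOMATIC_CALLERS
    if unknown:
        raise ValueError(f"unknown somatic caller id(s): {sorted(unknown)}")

    candidates: list[ConsensusVariant] = []
    groups = _group_by_key(calls)
    for key in sorted(groups):
        records = groups[key]
        is_snv = records[0].is_snv
        admissible = SOMATIC_SNV_CALLERS if is_snv else SOMATIC_INDEL_CALLERS
        supporters = frozenset(r.caller for r in records) & admissible
        rep = _representative([r for r in records if r.caller in supporters] or records)
        filters = {
            "min_callers": len(supporters) >= min_callers,
            "normal_vaf": rep.normal_depth > 0 and rep.normal_vaf <= max_normal_vaf,
            "tumor_vaf": rep.tumor_depth > 0 and rep.tumor_vaf >= min_tumor_vaf,
            "tumor_depth": rep.tumor_depth >= min_tumor_depth,
            "normal_depth": rep.normal_depth >= min_normal_depth,
            "indel_length": is_snv or rep.indel_length < max_indel_length,
            "exonic": rep.exonic,
            "dbsnp_not_cosmic": not (rep.in_dbsnp and not rep.in_cosmic),
        }
        candidates.append(ConsensusVariant(record=rep, callers=supporters, filters=filters))

    kept = [c for c in candidates if c.passed]
    if return_audit:
        audit = pd.DataFrame(
            [
                {
                    "chrom": c.record.chrom,
                    "pos": c.record.pos,
                    "ref": c.record.ref,
                    "alt": c.record.alt,
                    "callers": ",".join(sorted(c.callers)),
                    **c.filters,
                    "pass": c.passed,
                }
                for c in candidates
            ]
        )
        return kept, audit
    return kept


def filter_tumor_only(
    calls: list[VariantRecord],
    site_readcounts: dict[tuple[str, int, str, str], tuple[int, int]],
    *,
    panel_of_normals: frozenset | set = frozenset(),
    min_coverage: int = 20,
    min_alt_reads: int = 3,
    min_vaf: float = 0.1,
) -> list[VariantRecord]:
    """Tumor-only call filter against readcount-verified site evidence.

    Keeps a call iff its readcount-verified site coverage is >= 20x, alt
    reads are strictly > 3 and tumor VAF >= 0.1, and the site is not in
    the panel of normals. Sites absent from the readcount table fail.
    """
    kept = []
    for rec in calls:
        if rec.key in panel_of_normals:
            continue
        if rec.key not in site_readcounts:
            continue
        depth, alt = site_readcounts[rec.key]
        if depth < min_coverage or alt <= min_alt_reads:
            continue
        if depth == 0 or alt / depth < min_vaf:
            continue
        kept.append(rec)
    return kept


def rescue_variants(
    driver_variants: list[VariantRecord],
    per_sample_readcounts: dict[tuple[str, tuple], tuple[int, int]],
    existing_calls: list[VariantRecord],
    *,
    min_alt_reads: int = 2,
    min_vaf: float = 0.02,
) -> RescueResult:
    """Rescue cohort-detected driver variants in samples lacking a call.

    For every (sample, driver variant) pair: a sample that already carries
    the call passes it through unchanged; otherwise a rescued record
    (``rescued=True``) is emitted when the sample's readcount evidence at
    the site shows at least ``min_alt_reads`` alt reads and a VAF of at
    least ``min_vaf``. Readcounts are expected to have been produced with
    mapping- and base-quality floors of 20. Variants absent from the
    readcount table are recorded as unassessable, not rescued.
    """
    called = {(rec.sample, rec.key) for rec in existing_calls}
    samples = sorted({s for (s, _k) in per_sample_readcounts} | {r.sample for r in existing_calls if r.sample})
    out = list(existing_calls)
    unassessable: list[tuple[str, tuple]] = []
    for sample in samples:
        for drv in driver_variants:
            if (sample, drv.key) in called:
                continue
            entry = per_sample_readcounts.get((sample, drv.key))
            if entry is None:
                unassessable.append((sample, drv.key))
                continue
            depth, alt = entry
            if alt >= min_alt_reads and depth > 0 and alt / depth >= min_vaf:
                out.append(
                    replace(
                        drv,
                        sample=sample,
                        tumor_depth=depth,
                        tumor_alt=alt,
                        rescued=True,
                    )
                )
    return RescueResult(calls=out, unassessable=unassessable)


def _coding_trees(
    coding_intervals: dict[str, list[tuple[int, int]]], flank: int
) -> dict[str, IntervalTree]:
    trees = {}
    for chrom, ivals in coding_intervals.items():
        trees[chrom] = IntervalTree.from_tuples(
            (max(0, s - flank), e + flank) for s, e in ivals if e > s
        )
    return trees


def _in_coding(rec: VariantRecord, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(rec.chrom)
    if tree is None:
        return False
    # 1-based inclusive variant span -> 0-based half-open
    start0 = rec.pos - 1
    end0 = rec.pos - 1 + max(len(rec.ref), 1)
    return bool(tree.overlap(start0, end0))


def merge_germline_calls(
    calls: list[VariantRecord],
    coding_intervals: dict[str, list[tuple[int, int]]],
    *,
    splice_flank: int = 2,
    min_coverage: int = 10,
    min_vaf: float = 0.20,
    min_alt_depth: int = 5,
    max_indel_length: int = 100,
    return_audit: bool = False,
):
    """Merge germline calls from GATK, VarScan and Pindel.

    SNVs are the union of GATK and VarScan calls; indels are kept iff
    called by Pindel or by at least two of {GATK, VarScan, Pindel}. The
    merged set then requires >= 10x coverage and >= 20% VAF in the normal
    (germline) sample, alt allelic depth >= 5 in both tumor and normal,
    location within the coding intervals padded by a 2 bp splice flank
    (BED 0-based half-open input), and indel length <= 100 bp.
    """
    unknown = {r.caller for r in calls} - GERMLINE_CALLERS
    if unknown:
        raise ValueError(f"unknown germline caller id(s): {sorted(unknown)}")
    trees = _coding_trees(coding_intervals, splice_flank)

    candidates: list[ConsensusVariant] = []
    groups = _group_by_key(calls)
    for key in sorted(groups):
        records = groups[key]
        supporters = frozenset(r.caller for r in records)
        rep = _representative(records)
        if rep.is_snv:
            caller_rule = bool(supporters & {"gatk", "varscan"})
        else:
            caller_rule = "pindel" in supporters or len(supporters) >= 2
        filters = {
            "caller_rule": caller_rule,
            "coverage": rep.normal_depth >= min_coverage,
            "vaf": rep.normal_depth > 0 and rep.normal_vaf >= min_vaf,
            "alt_depth_both": rep.normal_alt >= min_alt_depth and rep.tumor_alt >= min_alt_depth,
            "coding_region": _in_coding(rep, trees),
            "indel_length": rep.is_snv or rep.indel_length <= max_indel_length,
        }
        candidates.append(ConsensusVariant(record=rep, callers=supporters, filters=filters))

    kept = [c for c in candidates if c.passed]
    if return_audit:
        audit = pd.DataFrame(
            [
                {
                    "chrom": c.record.chrom,
                    "pos": c.record.pos,
                    "ref": c.record.ref,
                    "alt": c.record.alt,
                    "callers": ",".join(sorted(c.callers)),
                    **c.filters,
                    "pass": c.passed,
                }
                for c in candidates
            ]
        )
        return kept, audit
    return kept


def classify_pathogenicity(
    v: VariantRecord,
    *,
    mode: str = "paired",
    somatic_keys: frozenset | set = frozenset(),
    max_gnomad_af: float = 0.0005,
    min_alt_count: int = 5,
    min_vaf: float = 0.20,
) -> str:
    """Tier a germline variant: pathogenic / likely_pathogenic /
    prioritized_VUS / none.

    Gate (all modes): rare in gnomAD (AF <= 0.05%; a missing AF is treated
    as rare) and readcount-backed evidence of at least five alternative
    alleles and >= 20% VAF in both tumor and normal. Tiers: a known
    ClinVar-pathogenic variant is ``pathogenic``; else CharGer score > 8
    is ``likely_pathogenic``; else CharGer score > 4 is
    ``prioritized_VUS``; else ``none``.

    In ``mode="tumor_only"`` (no matched normal was available) variants
    also present in the somatic consensus set are removed, as are variants
    absent from gnomAD unless reported in COSMIC.
    """
    if mode not in ("paired", "tumor_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if v.gnomad_af is not None and v.gnomad_af > max_gnomad_af:
        return "none"
    if not (v.normal_alt >= min_alt_count and v.tumor_alt >= min_alt_count):
        return "none"
    if not (
        v.normal_depth > 0
        and v.tumor_depth > 0
        and v.normal_vaf >= min_vaf
        and v.tumor_vaf >= min_vaf
    ):
        return "none"
    if mode == "tumor_only":
        if v.key in somatic_keys:
            return "none"
        if v.gnomad_af is None and not v.in_cosmic:
            return "none"
    if v.clinvar == "pathogenic":
        return "pathogenic"
    if v.charger_score is not None and v.charger_score > 8:
        return "likely_pathogenic"
    if v.charger_score is not None and v.charger_score > 4:
        return "prioritized_VUS"
    return "none"


def loh_fisher(variants: list[VariantRecord], fdr_threshold: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher exact LOH test per variant with BH adjustment.

    Each variant contributes the 2x2 table (tumor alt, tumor ref) vs
    (normal alt, normal ref); the one-sided alternative is that the tumor
    alt fraction exceeds the normal's (hypergeometric upper tail). BH
    adjustment is applied across all testable variants of the call; a
    variant with a zero-depth sample gets missing p/FDR and is excluded
    from the adjustment family.
    """
    rows = []
    for v in variants:
        if v.tumor_depth == 0 or v.normal_depth == 0:
            p = math.nan
        else:
            table = [
                [v.tumor_alt, v.tumor_depth - v.tumor_alt],
                [v.normal_alt, v.normal_depth - v.normal_alt],
            ]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "tumor_vaf": v.tumor_vaf,
                "normal_vaf": v.normal_vaf,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    if len(out):
        testable = out["p"].notna()
        if testable.any():
            out.loc[testable, "fdr"] = multipletests(
                out.loc[testable, "p"].to_numpy(), method="fdr_bh"
            )[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def count_cell_alleles(
    observations: list[tuple[str, str, str]],
    ref_base: str,
    alt_base: str,
    variant_key: tuple[str, int, str, str],
) -> list[CellAlleleCount]:
    """Tally unique molecules per cell supporting ref vs alt.

    ``observations`` are (cell barcode, molecular barcode, base) triples
    already filtered for quality. Each molecule votes once: reads of the
    same (cell, UMI) are resolved by majority between ref- and alt-matching
    bases; ties (including molecules with no ref/alt-matching base) are
    discarded.
    """
    votes: dict[tuple[str, str], list[str]] = defaultdict(list)
    for barcode, umi, base in observations:
        votes[(barcode, umi)].append(base)
    per_cell: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for (barcode, _umi), bases in votes.items():
        n_ref = sum(b == ref_base for b in bases)
        n_alt = sum(b == alt_base for b in bases)
        if n_ref > n_alt:
            per_cell[barcode][0] += 1
        elif n_alt > n_ref:
            per_cell[barcode][1] += 1
        # tie (including 0/0): molecule discarded
    return [
        CellAlleleCount(barcode=bc, variant_key=variant_key, ref_reads=r, alt_reads=a)
        for bc, (r, a) in sorted(per_cell.items())
    ]


def map_variants_to_cells(
    alignments,
    variants: list[VariantRecord],
    *,
    cell_tag: str = "CB",
    umi_tag: str = "UB",
    min_mapping_quality: int = 20,
    min_base_quality: int = 20,
) -> list[CellAlleleCount]:
    """Barcode-resolved allele counting for SNVs from tagged alignments.

    ``alignments`` is a path to a SAM/BAM file or an open
    :class:`pysam.AlignmentFile`. For every SNV, reads covering the site
    that carry cell- and molecular-barcode tags and clear the mapping- and
    base-quality floors contribute their base; molecules then vote per
    :func:`count_cell_alleles`.
    """
    import pysam

    snvs = [v for v in variants if v.is_snv]
    if len(snvs) != len(variants):
        raise ValueError("only SNVs are supported for variant-to-cell mapping")

    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments), "r") if own else alignments
    obs: dict[tuple, list[tuple[str, str, str]]] = {v.key: [] for v in snvs}
    by_chrom: dict[str, list[VariantRecord]] = defaultdict(list)
    for v in snvs:
        by_chrom[v.chrom].append(v)
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            if not (read.has_tag(cell_tag) and read.has_tag(umi_tag)):
                continue
            chrom = read.reference_name
            if chrom not in by_chrom:
                continue
            pairs = {
                rpos: qpos
                for qpos, rpos in read.get_aligned_pairs(matches_only=True)
            }
            quals = read.query_qualities
            seq = read.query_sequence
            for v in by_chrom[chrom]:
                qpos = pairs.get(v.pos - 1)  # 1-based variant -> 0-based ref
                if qpos is None:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                obs[v.key].append(
                    (read.get_tag(cell_tag), read.get_tag(umi_tag), seq[qpos])
                )
    finally:
        if own:
            af.close()

    counts: list[CellAlleleCount] = []
    for v in snvs:
        counts.extend(count_cell_alleles(obs[v.key], v.ref, v.alt, v.key))
    return counts


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "caller", "tumor_depth", "tumor_alt",
    "normal_depth", "normal_alt", "exonic", "in_dbsnp", "in_cosmic",
    "gnomad_af", "clinvar", "charger_score", "sample", "rescued",
]


def write_variants_tsv(records: list[VariantRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in _TSV_COLUMNS})
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    table = pd.read_csv(path, sep="\t")
    records = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        gnomad = d.get("gnomad_af")
        charger = d.get("charger_score")
        sample = d.get("sample")
        records.append(
            VariantRecord(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                caller=str(d["caller"]),
                tumor_depth=int(d["tumor_depth"]),
                tumor_alt=int(d["tumor_alt"]),
                normal_depth=int(d["normal_depth"]),
                normal_alt=int(d["normal_alt"]),
                exonic=bool(d["exonic"]),
                in_dbsnp=bool(d["in_dbsnp"]),
                in_cosmic=bool(d["in_cosmic"]),
                gnomad_af=None if pd.isna(gnomad) else float(gnomad),
                clinvar=str(d.get("clinvar", "none")),
                charger_score=None if pd.isna(charger) else float(charger),
                sample=None if pd.isna(sample) else str(sample),
                rescued=bool(d.get("rescued", False)),
            )
        )
    return records


def read_vcf_calls(
    path,
    caller: str,
    *,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> list[VariantRecord]:
    """Minimal VCF reader: CHROM/POS/REF/ALT plus per-sample AD and DP.

    Sample names default to the first (tumor) and second (normal) sample
    columns. Multi-allelic sites are split into one record per alt allele.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        t_name = tumor_sample or (samples[0] if samples else None)
        n_name = normal_sample or (samples[1] if len(samples) > 1 else None)
        for site in vcf:
            for i, alt in enumerate(site.alts or ()):
                t_depth = t_alt = n_depth = n_alt = 0
                if t_name is not None:
                    s = site.samples[t_name]
                    ad = s.get("AD")
                    t_depth = int(s.get("DP") or (sum(ad) if ad else 0))
                    t_alt = int(ad[i + 1]) if ad and len(ad) > i + 1 else 0
                if n_name is not None:
                    s = site.samples[n_name]
                    ad = s.get("AD")
                    n_depth = int(s.get("DP") or (sum(ad) if ad else 0))
                    n_alt = int(ad[i + 1]) if ad and len(ad) > i + 1 else 0
                records.append(
                    VariantRecord(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=alt,
                        caller=caller,
                        tumor_depth=t_depth,
                        tumor_alt=t_alt,
                        normal_depth=n_depth,
                        normal_alt=n_alt,
                    )
                )
    return records
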