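"""Consensus variant filters against truth-table oracles; LOH closed form."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bclineage.synthetic import CallerProfile, TrueVariant, generate_caller_calls
from bclineage.variants import (
    VariantRecord,
    classify_pathogenicity,
    count_cell_alleles,
    filter_tumor_only,
    loh_fisher,
    map_variants_to_cells,
    merge_germline_calls,
    merge_somatic_calls,
    read_variants_tsv,
    rescue_variants,
    trim_alleles,
    write_variants_tsv,
)


def _somatic(caller="strelka", **kw):
    base = dict(
        chrom="chr1", pos=100, ref="A", alt="T", caller=caller,
        tumor_depth=50, tumor_alt=15, normal_depth=30, normal_alt=0,
        exonic=True, in_dbsnp=False, in_cosmic=False,
    )
    base.update(kw)
    return VariantRecord(**base)


# ----------------------------------------------------------- key handling

def test_trim_alleles_suffix_and_prefix():
    # shared suffix stripped first, then shared prefix with position advance
    assert trim_alleles(100, "ATG", "AG") == (100, "AT", "A")
    assert trim_alleles(100, "CA", "CT") == (101, "A", "T")
    assert trim_alleles(100, "A", "T") == (100, "A", "T")
    assert trim_alleles(100, "ACCC", "ACC") == (100, "AC", "A")
    assert trim_alleles(100, "TCAG", "TCG") == (101, "CA", "C")


def test_different_representations_merge_to_one_key():
    a = _somatic(caller="strelka", pos=100, ref="CAG", alt="CG")
    b = _somatic(caller="varscan", pos=99, ref="TCAG", alt="TCG")
    c = _somatic(caller="pindel", pos=100, ref="CAG", alt="CG")
    assert a.key == b.key == c.key
    kept = merge_somatic_calls([a, b, c])
    assert len(kept) == 1 and kept[0].callers >= {"strelka", "varscan"}


def test_inconsistent_ref_allele_rejected():
    a = _somatic(caller="strelka")
    b = _somatic(caller="mutect", ref="G", alt="T")
    with pytest.raises(ValueError, match="inconsistent ref"):
        merge_somatic_calls([a, b])


def test_unknown_caller_rejected():
    with pytest.raises(ValueError, match="unknown somatic caller"):
        merge_somatic_calls([_somatic(caller="freebayes")])


# -------------------------------------------------------- somatic filter

def test_clean_two_caller_snv_kept():
    calls = [_somatic("strelka", tumor_alt=15), _somatic("mutect", tumor_alt=12)]
    (kept,) = merge_somatic_calls(calls)
    assert kept.callers == {"strelka", "mutect"}


def test_single_caller_dropped():
    assert merge_somatic_calls([_somatic("mutect")]) == []


def test_pindel_not_admissible_for_snvs():
    calls = [_somatic("strelka"), _somatic("pindel")]
    assert merge_somatic_calls(calls) == []


def test_mutect_not_admissible_for_indels():
    calls = [
        _somatic("strelka", ref="AT", alt="A"),
        _somatic("mutect", ref="AT", alt="A"),
    ]
    assert merge_somatic_calls(calls) == []
    calls[1] = _somatic("pindel", ref="AT", alt="A")
    assert len(merge_somatic_calls(calls)) == 1


def somatic_oracle(rep, n_callers, is_snv):
    """Independent restatement of the somatic filter clauses."""
    t_vaf = rep.tumor_alt / rep.tumor_depth if rep.tumor_depth else float("nan")
    n_vaf = rep.normal_alt / rep.normal_depth if rep.normal_depth else float("nan")
    return (
        n_callers >= 2
        and rep.normal_depth > 0 and n_vaf <= 0.02
        and rep.tumor_depth > 0 and t_vaf >= 0.05
        and rep.tumor_depth >= 14
        and rep.normal_depth >= 8
        and (is_snv or abs(len(rep.ref) - len(rep.alt)) < 100)
        and rep.exonic
        and not (rep.in_dbsnp and not rep.in_cosmic)
    )


def test_somatic_filter_equals_truth_table_oracle():
    """Every threshold exercised at value-1 / value / value+1 on a grid."""
    grid = itertools.product(
        [1, 2],                     # caller count
        [13, 14, 15],               # tumor depth
        [7, 8, 9],                  # normal depth
        [0.04, 0.05, 0.3],          # tumor VAF
        [0.0, 0.02, 0.03],          # normal VAF
        [True, False],              # exonic
        [(False, False), (True, False), (True, True)],  # dbSNP/COSMIC
    )
    pos = 1000
    calls, expected_keys = [], set()
    for n_callers, td, nd, tv, nv, exonic, (dbsnp, cosmic) in grid:
        pos += 1
        rec_kw = dict(
            chrom="chr1", pos=pos, ref="A", alt="T",
            tumor_depth=td, tumor_alt=round(tv * td),
            normal_depth=nd, normal_alt=round(nv * nd),
            exonic=exonic, in_dbsnp=dbsnp, in_cosmic=cosmic,
        )
        for caller in ["strelka", "mutect"][:n_callers]:
            calls.append(VariantRecord(caller=caller, **rec_kw))
        rep = VariantRecord(caller="strelka", **rec_kw)
        if somatic_oracle(rep, n_callers, is_snv=True):
            expected_keys.add(rep.key)
    kept = {c.key for c in merge_somatic_calls(calls)}
    assert kept == expected_keys
    assert expected_keys  # the grid must contain survivors


def test_somatic_indel_length_boundary():
    long_ref = "A" * 101
    calls = [
        _somatic(c, ref=long_ref, alt="A") for c in ("strelka", "varscan")
    ]  # indel length 100 -> dropped (strict < 100)
    assert merge_somatic_calls(calls) == []
    calls = [_somatic(c, ref="A" * 100, alt="A") for c in ("strelka", "varscan")]
    assert len(merge_somatic_calls(calls)) == 1  # length 99 kept


def test_merge_order_invariant_and_idempotent(rng):
    tvs = [TrueVariant("chr1", 1000 + i, "A", "T") for i in range(20)]
    profiles = [CallerProfile(n, 0.8, 2.0) for n in ("strelka", "varscan", "mutect", "pindel")]
    calls = generate_caller_calls(tvs, profiles, seed=3)
    kept = merge_somatic_calls(calls)
    shuffled = [calls[i] for i in rng.permutation(len(calls))]
    kept2 = merge_somatic_calls(shuffled)
    assert [c.key for c in kept] == [c.key for c in kept2]


def test_perfect_callers_recover_planted_set():
    tvs = [TrueVariant("chr1", 1000 + i, "A", "T", tumor_vaf=0.4) for i in range(25)]
    profiles = [CallerProfile(n, 1.0, 0.0) for n in ("strelka", "varscan", "mutect", "pindel")]
    calls = generate_caller_calls(tvs, profiles, seed=8)
    kept = merge_somatic_calls(calls)
    assert {c.key for c in kept} == {("chr1", 1000 + i, "A", "T") for i in range(25)}


def test_insensitive_callers_fail_two_caller_rule():
    tvs = [TrueVariant("chr1", 1000, "A", "T")]
    profiles = [
        CallerProfile("strelka", 1.0, 0.0),
        CallerProfile("varscan", 0.0, 0.0),
        CallerProfile("mutect", 0.0, 0.0),
        CallerProfile("pindel", 0.0, 0.0),
    ]
    calls = generate_caller_calls(tvs, profiles, seed=1)
    assert merge_somatic_calls(calls) == []


def test_mixed_profile_equals_bruteforce_on_emitted_records():
    tvs = [TrueVariant("chr1", 1000 + i, "A", "T", tumor_vaf=0.35) for i in range(30)]
    profiles = [
        CallerProfile("strelka", 0.9, 3.0),
        CallerProfile("varscan", 0.7, 1.0),
        CallerProfile("mutect", 0.8, 2.0),
        CallerProfile("pindel", 0.5, 0.0),
    ]
    calls = generate_caller_calls(tvs, profiles, seed=77)
    # brute-force oracle over emitted records
    by_key = {}
    for r in calls:
        by_key.setdefault(r.key, []).append(r)
    expected = set()
    for key, records in by_key.items():
        supporters = {r.caller for r in records} & {"strelka", "varscan", "mutect"}
        sup_records = [r for r in records if r.caller in supporters] or records
        rep = max(sup_records, key=lambda r: (r.tumor_depth, r.caller))
        if somatic_oracle(rep, len(supporters), is_snv=True):
            expected.add(key)
    assert {c.key for c in merge_somatic_calls(calls)} == expected


# ------------------------------------------------------ tumor-only filter

def test_tumor_only_boundaries():
    rec = _somatic("mutect")
    key = rec.key
    kept = filter_tumor_only([rec], {key: (20, 4)})
    assert len(kept) == 1  # cov=20, alt=4, vaf=0.2: all boundaries pass
    assert filter_tumor_only([rec], {key: (20, 3)}) == []      # alt>3 strict
    assert filter_tumor_only([rec], {key: (19, 4)}) == []      # cov >= 20
    assert filter_tumor_only([rec], {key: (50, 4)}) == []      # vaf 0.08 < 0.1
    assert filter_tumor_only([rec], {key: (40, 4)}) == [rec]   # vaf 0.1 passes
    assert filter_tumor_only([rec], {key: (20, 4)}, panel_of_normals={key}) == []


def test_tumor_only_random_grid_equals_oracle(rng):
    records, rc = [], {}
    for i in range(300):
        rec = _somatic("mutect", pos=2000 + i)
        depth = int(rng.integers(10, 40))
        alt = int(rng.integers(0, depth + 1))
        records.append(rec)
        rc[rec.key] = (depth, alt)
    kept = filter_tumor_only(records, rc)
    expected = [
        r for r in records
        if rc[r.key][0] >= 20 and rc[r.key][1] > 3 and rc[r.key][1] / rc[r.key][0] >= 0.1
    ]
    assert kept == expected


# ---------------------------------------------------------------- rescue

def test_rescue_rules():
    driver = _somatic("mutect", pos=500, sample=None)
    called = [_somatic("mutect", pos=500, sample="S1")]
    rc = {
        ("S1", driver.key): (50, 20),
        ("S2", driver.key): (50, 5),   # alt 5/50, vaf 0.1 -> rescued
        ("S3", driver.key): (50, 0),   # no alt reads -> not rescued
        ("S4", driver.key): (40, 1),   # 1 alt read < 2 -> not rescued
    }
    result = rescue_variants([driver], rc, called)
    by_sample = {r.sample: r for r in result.calls}
    assert by_sample["S1"].rescued is False     # passthrough unchanged
    assert by_sample["S2"].rescued is True
    assert "S3" not in by_sample and "S4" not in by_sample
    assert result.unassessable == []


def test_rescue_unassessable_when_absent_from_readcounts():
    driver = _somatic("mutect", pos=500)
    rc = {("S1", ("chrX", 1, "A", "T")): (50, 10)}
    result = rescue_variants([driver], rc, [])
    assert ("S1", driver.key) in result.unassessable


# ------------------------------------------------------- germline filter

CODING = {"chr1": [(0, 1_000_000)]}


def _germline(caller="gatk", **kw):
    base = dict(
        chrom="chr1", pos=100, ref="A", alt="T", caller=caller,
        tumor_depth=60, tumor_alt=25, normal_depth=60, normal_alt=25,
    )
    base.update(kw)
    return VariantRecord(**base)


def test_pindel_only_indel_kept_but_gatk_only_dropped():
    pindel_indel = _germline("pindel", ref="AT", alt="A")
    (kept,) = merge_germline_calls([pindel_indel], CODING)
    assert kept.callers == {"pindel"}
    gatk_indel = _germline("gatk", ref="AT", alt="A")
    assert merge_germline_calls([gatk_indel], CODING) == []
    two_of_three = [_germline("gatk", ref="AT", alt="A"), _germline("varscan", ref="AT", alt="A")]
    assert len(merge_germline_calls(two_of_three, CODING)) == 1


def test_germline_snv_union_of_gatk_varscan():
    assert len(merge_germline_calls([_germline("gatk")], CODING)) == 1
    assert len(merge_germline_calls([_germline("varscan")], CODING)) == 1
    assert merge_germline_calls([_germline("pindel")], CODING) == []


def test_germline_splice_flank_boundary():
    coding = {"chr1": [(199, 300)]}  # 0-based exon [199,300) = 1-based 200..300
    inside_flank = _germline("gatk", pos=198)   # 2 bp before exon start
    outside = _germline("gatk", pos=197)        # 3 bp before: outside flank
    assert len(merge_germline_calls([inside_flank], coding)) == 1
    assert merge_germline_calls([outside], coding) == []


def test_germline_grid_equals_truth_table_oracle():
    grid = itertools.product(
        [9, 10, 11],        # normal depth (coverage)
        [0.19, 0.20, 0.25],  # normal VAF
        [4, 5, 6],          # alt depth both samples
        [True, False],      # in coding region
    )
    pos_in, pos_out = 1000, 2_000_000
    calls, expected = [], set()
    for nd_base, nv, alt, coding in grid:
        # scale depth so that requested VAF and alt counts are representable
        alt_n = alt
        nd = max(nd_base, int(np.ceil(alt_n / max(nv, 1e-9))))
        # adjust alt to achieve VAF exactly when possible
        alt_n = int(round(nv * nd))
        if alt_n == 0:
            continue
        pos = pos_in if coding else pos_out
        pos_in += 1
        pos_out += 1
        rec = VariantRecord(
            chrom="chr1", pos=pos, ref="A", alt="T", caller="gatk",
            tumor_depth=nd, tumor_alt=alt_n, normal_depth=nd, normal_alt=alt_n,
        )
        calls.append(rec)
        ok = (
            rec.normal_depth >= 10
            and rec.normal_vaf >= 0.20
            and rec.normal_alt >= 5 and rec.tumor_alt >= 5
            and coding
        )
        if ok:
            expected.add(rec.key)
    kept = {c.key for c in merge_germline_calls(calls, CODING)}
    assert kept == expected and expected


def test_germline_indel_length_boundary_inclusive():
    ref100 = "A" * 101  # indel length 100 -> kept (<= 100)
    kept = merge_germline_calls([_germline("pindel", ref=ref100, alt="A")], CODING)
    assert len(kept) == 1
    ref101 = "A" * 102  # indel length 101 -> dropped
    assert merge_germline_calls([_germline("pindel", ref=ref101, alt="A")], CODING) == []


# ------------------------------------------------- pathogenicity tiers

def _path_variant(**kw):
    base = dict(
        chrom="chr1", pos=10, ref="A", alt="T", caller="gatk",
        tumor_depth=60, tumor_alt=25, normal_depth=60, normal_alt=25,
        gnomad_af=1e-5,
    )
    base.update(kw)
    return VariantRecord(**base)


def test_clinvar_pathogenic_tier():
    v = _path_variant(clinvar="pathogenic")
    assert classify_pathogenicity(v) == "pathogenic"


def test_charger_score_boundary_strict():
    assert classify_pathogenicity(_path_variant(charger_score=9)) == "likely_pathogenic"
    assert classify_pathogenicity(_path_variant(charger_score=8)) == "prioritized_VUS"
    assert classify_pathogenicity(_path_variant(charger_score=5)) == "prioritized_VUS"
    assert classify_pathogenicity(_path_variant(charger_score=4)) == "none"


def test_pathogenicity_decision_table_oracle():
    """Gate x tier grid equals an independent decision-table oracle."""
    afs = [None, 0.0004, 0.0005, 0.0006]
    alts = [4, 5, 6]
    vafs = [0.19, 0.20, 0.30]
    clinvars = ["none", "pathogenic"]
    chargers = [None, 4, 5, 8, 9]
    for af, alt, vaf, clinvar, charger in itertools.product(
        afs, alts, vafs, clinvars, chargers
    ):
        depth = max(60, int(np.ceil(alt / vaf)))
        alt_n = int(round(vaf * depth))
        v = _path_variant(
            gnomad_af=af, clinvar=clinvar, charger_score=charger,
            tumor_depth=depth, tumor_alt=alt_n if alt >= 5 else alt,
            normal_depth=depth, normal_alt=alt_n if alt >= 5 else alt,
        )
        gate = (
            (v.gnomad_af is None or v.gnomad_af <= 0.0005)
            and v.tumor_alt >= 5 and v.normal_alt >= 5
            and v.tumor_vaf >= 0.20 and v.normal_vaf >= 0.20
        )
        if not gate:
            expected = "none"
        elif clinvar == "pathogenic":
            expected = "pathogenic"
        elif charger is not None and charger > 8:
            expected = "likely_pathogenic"
        elif charger is not None and charger > 4:
            expected = "prioritized_VUS"
        else:
            expected = "none"
        assert classify_pathogenicity(v) == expected


def test_tumor_only_mode_extra_filters():
    v = _path_variant(clinvar="pathogenic")
    assert classify_pathogenicity(v, mode="tumor_only", somatic_keys={v.key}) == "none"
    absent = _path_variant(clinvar="pathogenic", gnomad_af=None, in_cosmic=False)
    assert classify_pathogenicity(absent, mode="tumor_only") == "none"
    cosmic = _path_variant(clinvar="pathogenic", gnomad_af=None, in_cosmic=True)
    assert classify_pathogenicity(cosmic, mode="tumor_only") == "pathogenic"


# ------------------------------------------------------------ LOH test

def hypergeom_tail(t_alt, t_ref, n_alt, n_ref):
    """Closed-form one-sided tail: P(X >= t_alt) for X ~ Hypergeom."""
    total = t_alt + t_ref + n_alt + n_ref
    draws = t_alt + t_ref
    successes = t_alt + n_alt
    return float(stats.hypergeom.sf(t_alt - 1, total, successes, draws))


def test_loh_equal_proportions_not_small():
    v = VariantRecord("chr1", 1, "A", "T", "gatk", 200, 100, 200, 100)
    p = loh_fisher([v])["p"].iloc[0]
    assert p > 0.4


def test_loh_matches_hypergeometric_tail():
    v = VariantRecord("chr1", 1, "A", "T", "gatk", 100, 90, 100, 50)
    p = loh_fisher([v])["p"].iloc[0]
    assert p == pytest.approx(hypergeom_tail(90, 10, 50, 50), rel=1e-10)


def test_loh_random_tables_match_closed_form(rng):
    variants = []
    for i in range(200):
        td = int(rng.integers(10, 200))
        nd = int(rng.integers(10, 200))
        variants.append(
            VariantRecord("chr1", i + 1, "A", "T", "gatk",
                          td, int(rng.integers(0, td + 1)),
                          nd, int(rng.integers(0, nd + 1)))
        )
    out = loh_fisher(variants)
    for row, v in zip(out.itertuples(index=False), variants):
        expected = hypergeom_tail(
            v.tumor_alt, v.tumor_depth - v.tumor_alt,
            v.normal_alt, v.normal_depth - v.normal_alt,
        )
        assert row.p == pytest.approx(expected, rel=1e-10)
    # BH matches the definitional step-up formula
    p = out["p"].to_numpy()
    m = len(p)
    order = np.argsort(p)
    bh = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        running = min(running, p[order[rank_idx]] * m / (rank_idx + 1))
        bh[order[rank_idx]] = running
    np.testing.assert_allclose(out["fdr"].to_numpy(), bh, rtol=1e-12)
    assert (out["fdr"] >= out["p"] - 1e-15).all()
    assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


def test_loh_single_variant_fdr_equals_p():
    v = VariantRecord("chr1", 1, "A", "T", "gatk", 100, 90, 100, 50)
    out = loh_fisher([v])
    assert out["fdr"].iloc[0] == pytest.approx(out["p"].iloc[0])


def test_loh_zero_depth_reported_missing():
    v = VariantRecord("chr1", 1, "A", "T", "gatk", 0, 0, 100, 50)
    out = loh_fisher([v])
    assert np.isnan(out["p"].iloc[0]) and np.isnan(out["fdr"].iloc[0])


# ----------------------------------------------- variant-to-cell mapping

def test_molecule_votes():
    obs = [("cell1", f"umi{i}", "T") for i in range(3)]
    (count,) = count_cell_alleles(obs, "A", "T", ("chr1", 100, "A", "T"))
    assert (count.ref_reads, count.alt_reads) == (0, 3)


def test_intra_molecule_tie_discarded():
    obs = [("cell1", "umi1", "A"), ("cell1", "umi1", "T"), ("cell1", "umi2", "A")]
    (count,) = count_cell_alleles(obs, "A", "T", ("chr1", 100, "A", "T"))
    assert (count.ref_reads, count.alt_reads) == (1, 0)


def test_intra_molecule_majority_wins():
    obs = [("c", "u", "T"), ("c", "u", "T"), ("c", "u", "A")]
    (count,) = count_cell_alleles(obs, "A", "T", ("chr1", 100, "A", "T"))
    assert (count.ref_reads, count.alt_reads) == (0, 1)


def _write_sam(path, reads):
    header = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr1\tLN:10000\n"
    with open(path, "w") as fh:
        fh.write(header)
        for name, pos, seq, cb, ub, mapq in reads:
            fh.write(
                f"{name}\t0\tchr1\t{pos}\t{mapq}\t{len(seq)}M\t*\t0\t0\t{seq}\t"
                f"{'I' * len(seq)}\tCB:Z:{cb}\tUB:Z:{ub}\n"
            )


def test_map_variants_to_cells_from_sam(tmp_path, rng):
    """Counts from a tagged SAM equal a per-molecule brute-force tally."""
    variant = VariantRecord("chr1", 105, "A", "T", "mutect", 10, 5, 10, 0)
    reads = []
    truth: dict[tuple[str, str], list[str]] = {}
    for i in range(120):
        cb = f"CELL{int(rng.integers(4))}"
        ub = f"UMI{int(rng.integers(30))}"
        base = str(rng.choice(["A", "T", "G"], p=[0.45, 0.45, 0.1]))
        seq = "C" * 4 + base + "C" * 5  # read starts at 101; offset 4 = pos 105
        reads.append((f"r{i}", 101, seq, cb, ub, 60))
        truth.setdefault((cb, ub), []).append(base)
    # low-mapq read must be ignored
    reads.append(("rlow", 101, "C" * 4 + "T" + "C" * 5, "CELL0", "UMIX", 5))
    path = tmp_path / "reads.sam"
    _write_sam(path, reads)
    counts = map_variants_to_cells(path, [variant])
    expected: dict[str, list[int]] = {}
    for (cb, _ub), bases in truth.items():
        n_ref = bases.count("A")
        n_alt = bases.count("T")
        cell = expected.setdefault(cb, [0, 0])
        if n_ref > n_alt:
            cell[0] += 1
        elif n_alt > n_ref:
            cell[1] += 1
    got = {c.barcode: [c.ref_reads, c.alt_reads] for c in counts}
    assert got == {k: v for k, v in expected.items() if v != [0, 0]}


# ------------------------------------------------------------------ I/O

def test_variant_tsv_roundtrip(tmp_path):
    records = [
        _somatic("strelka"),
        _somatic("varscan", pos=200, gnomad_af=0.001, charger_score=9.0,
                 clinvar="pathogenic", sample="S1", rescued=True),
    ]
    path = tmp_path / "variants.tsv"
    write_variants_tsv(records, path)
    loaded = read_variants_tsv(path)
    assert loaded == records
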