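# Methods

This note documents the models and procedures the package implements,
the defaults and why, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Consensus PAM50 subtyping

Nearest-centroid classification assigns a 50-gene profile to the subtype
whose centroid it correlates with best. Spearman correlation is the
default metric (it matches the distributed reference implementation of
the classifier and is invariant to monotone transforms of the profile);
Pearson is available via `metric="pearson"`. A constant profile has no
defined correlation and is returned as `"unclassifiable"` rather than an
arbitrary subtype.

Median centering removes per-gene location so that cohort composition,
not absolute expression, drives the call. Because ER+ tumors dominate
most cohorts, the bulk pipeline bootstraps the medians: every iteration
uses all ER− samples plus an equal-size subset of ER+ samples drawn
uniformly without replacement from one seeded stream, so that with equal
ER+/ER− counts every iteration degenerates to the full cohort and the
consensus provably equals the single-pass call. The per-iteration medians
are computed from the bootstrap subset itself. Consensus ties are broken
by the higher mean correlation across iterations — deterministic and
rarely exercised. Defaults: `n_iter=1000`, as many iterations as the
procedure is usually run with; recovery on strongly structured data is
insensitive to this from roughly 50 iterations up.

Single-nucleus data are too sparse for per-cell correlation against
centroids, so tumor cells are classified at the cluster level: the mean
panel profile per cluster, centered with a supplied median vector, one
call per cluster, no bootstrap.

FPKM-UQ follows the GDC definition: `count × 10⁹ / (U × L)` with `U` the
75th percentile of the sample's nonzero (protein-coding, when a gene set
is supplied) counts and `L` the gene length, then `log₂(x+1)`. A sample
with no nonzero counts has an undefined upper quartile and is rejected.

## QC filters

All inequalities are applied strictly, exactly as printed in the
thresholds' source: a removal rule "< 300" fails 299 and keeps 300; a
keep rule "> 15" fails exactly 15. RNA thresholds are phrased as removal
conditions, ATAC thresholds as keep conditions; the package preserves
that phrasing in `RnaQcThresholds`/`AtacQcThresholds` so the boundary
semantics are fixed and tested at ±1 around every bound. Total transcript
counts and UMIs are kept as separate criteria (they are usually
correlated but are distinct input columns supplied by the caller). The
result carries a per-criterion removal count for QC reporting.

## Variant consensus

Variant identity is `(chrom, pos, ref, alt)` after parsimony trimming:
shared allele suffix removed first, then shared prefix with the position
advanced. This canonicalises caller representation differences that do
not require reference context; full left-alignment of indels in repeat
tracts would need the reference sequence, which the merge operations do
not take. Variant coordinates are 1-based inclusive; interval inputs
(coding regions, BED) are 0-based half-open, converted centrally.

Counts for a merged record are taken from the supporting caller with the
highest tumor depth (ties by caller id) — a deterministic rule where the
upstream pipelines are silent. Admissibility: SNVs from
strelka/varscan/mutect, indels from strelka/varscan/pindel; Strelka and
Strelka2 are one caller id. The indel-length bound differs between the
somatic filter (strictly < 100 bp) and the germline filter (≤ 100 bp,
"longer than 100 bp" removed) because that is how each rule is stated.

The germline coverage/VAF floor (≥ 10×, ≥ 20%) is applied to the normal
sample — germline calls originate there — while the allelic-depth floor
(alt ≥ 5) applies to tumor and normal, as stated. The rescue criterion
for cohort-detected driver variants in samples lacking a call is ≥ 2 alt
reads and VAF ≥ 0.02 (configurable): it matches the somatic
normal-contamination bound and avoids single-read artifacts. Sites absent
from the readcount table are reported unassessable rather than silently
dropped.

Pathogenicity tiers gate on rarity (gnomAD AF ≤ 0.05%, missing AF treated
as rare) and readcount support, then tier by ClinVar, CharGer > 8, and
CharGer > 4. In tumor-only mode, overlap with the somatic consensus and
absence from both gnomAD and COSMIC additionally remove a variant; note
the deliberate asymmetry with the rare-AF gate, where a missing gnomAD
AF passes.

The LOH test is the one-sided Fisher exact test of (tumor alt, tumor
ref) vs (normal alt, normal ref) against the alternative that the tumor
alt fraction is larger, i.e. the hypergeometric upper-tail probability.
The BH adjustment family is the variant list passed in one call; a
zero-depth sample yields a missing p excluded from the family.

Variant-to-cell mapping counts unique molecules per cell: reads sharing a
cell/UMI barcode pair vote once, intra-molecule ref/alt conflicts are
resolved by majority and ties discarded; mapping- and base-quality floors
default to 20/20.

## Peak atlas

Standardisation drops chrY peaks and peaks overlapping any N-gap
interval (N-gaps are interval lists; no sequence is needed), then resizes
to `[summit−250, summit+251)` — a symmetric 501 bp window. Peaks whose
resized window would cross a chromosome end are dropped, not clipped,
because clipping would break the fixed-width invariant.

Iterative overlap removal retains the highest-scoring remaining peak and
deletes everything sharing ≥ 1 base with it, until no peaks remain. The
implementation is the order-equivalent single pass in rank order (keep a
peak iff it overlaps nothing already kept), `O(n log n)` via a sorted
interval list, and is verified against the literal `O(n²)` greedy oracle.
Score ties break by (chrom, start) for determinism. Non-overlap of the
output is asserted on every run. Score-per-million normalises each
sample's scores to sum to 10⁶ so cohort merging can rank pooled peaks on
a comparable scale; the cohort atlas records the winning sample per
retained peak.

Promoter windows are strand-aware: 1,000 bp upstream to 100 bp
downstream of the TSS, flipped on the − strand, with both window ends
inclusive.

## Differential tests and lineage filters

`differential_expression` mirrors the conventions of the standard
single-cell toolkit: detection prefilter (`min_pct`, default 0.25 for
RNA), fold change as `log₂(mean(expm1 x)+1)` differences, Bonferroni
adjustment over the genes actually tested, and a choice of two-sided
Wilcoxon rank-sum (exact for small tie-free groups, via scipy) or a
binomial-GLM likelihood-ratio test of the group label on expression plus
optional covariates. Differential accessibility uses the logistic LRT
with the per-cell fraction of fragments in peaks as the latent covariate
and prefilters `min_pct = 0.1`, `min.diff.pct = 0.1` (absolute difference
of detection fractions).

The lineage gene filter is staged set algebra at padj < 0.05: start from
the lineage-group comparison (G1 = {basal-like tumor, LP} vs other
epithelium; G2 = {LumA, LumB, LM} vs rest), remove intra-lineage DEGs
(C1 = basal tumor vs LP, C2 = luminal tumors vs LM — cancer-generic, not
lineage), remove the opposite lineage-group set, require one-vs-rest
(A1) specificity to the lineage's tumor or progenitor and absence from
every other cell type's A1 set, and finally screen on pct.exp > 20 and
avg_log₂FC > 1. The luminal branch is implemented symmetrically (start
from G2); a literal reading of the source text would start both branches
from G1, which makes them identical at step 1 and contradicts their
distinct outputs — a `literal_text` flag reproduces that reading. The
mutual-exclusion clauses guarantee empty basal ∩ luminal output on any
input, which is tested. G3 ({LP, LM} vs rest) is accepted and exposed
but not consumed by the default procedure. Survivors are labelled
tumor-high / progenitor-high / shared from their A1 provenance.

The TF-motif filter takes chromVAR-style deviation matrices as input
(deviation computation itself is upstream). Step 1 keeps TFs enriched
(two-sided Wilcoxon, BH FDR < 0.05 over the whole assay, positive mean
difference) in tumor + putative origin vs the other epithelial groups;
step 2 removes TFs enriched in both basal-tumor-vs-LP and
luminal-tumor-vs-LM (cancer-generic); step 3 removes candidates enriched
in any non-lineage group's one-vs-rest comparison with mean difference
≥ 0.5. "Enriched" always requires a positive mean difference — the test
itself is two-sided, the direction filter follows it. Subtype-specific
TF lists additionally require a positive RNA fold change for the TF gene
in the same subtype-vs-rest comparison.

The surface-marker screen keeps a gene iff (1) in some sample its tumor
expression beats every other cell type present with all pairwise
comparisons significant; (2) tumor beats pooled non-tumor in ≥ 90% of
samples, significantly in ≥ 75%; and (3) it is in the supplied
cell-surface gene set (plain gene lists, unioned — the source databases
are inputs, not fetched). Samples without non-tumor cells leave the
denominators with a warning.

## CNV mapping

Segments map to genes/arms by the overlap-weighted mean ratio in linear
copy-ratio space (the upstream caller's 0.9/1.1 thresholds are linear);
a flag enables log₂-space averaging. Boundary values are neutral (strict
inequalities). Targets with no overlapping segment are "no-call".
Sample-adaptive bounds (1 ± z·σ of segment ratios) are available but off
by default — only the clamp rule is stated upstream, not the z
computation — and when on, they are clamped so the neutral zone is never
narrower than (0.9, 1.1).

## Imaging

The masked mean intensity standardises to the first 1,250 image lines,
thresholds the reference channel (E-cadherin for the MELK assay) at half
its cropped mean, and averages the target channel over mask pixels. A
pixel equal to the threshold is positive — a deterministic boundary, and
one consequence is that a nonnegative image can never produce an empty
mask (some pixel always reaches half the mean); the empty-mask warning
path exists for defensive completeness. The quantity is invariant to
global rescaling of the reference channel.

Region masks threshold each nominated channel at its manually set value
(automatic thresholding is deliberately not attempted), union them,
smooth with a Gaussian (σ = 2.0), re-binarise at 0.5, fill holes and
label with 8-connectivity (appropriate for closed duct rings).
Positive-cell fractions are per region, then averaged unweighted per
sample.

## Synthetic data

The generators define the study conditions for every test:

- **Expression cohorts**: negative-binomial counts with log-linear
  means (variance `μ + φμ²`, default dispersion φ = 0.15, typical of
  bulk RNA-seq replicate scatter). Each tumor entity's panel log₂-mean is
  a baseline plus its subtype centroid scaled by `effect_size` (the
  acceptance conditions use 60 samples, 5 subtypes, effect 5). Centroids
  are drawn standard normal per subtype and emitted together with the
  cohort median vector as a synthetic centroid reference — the published
  centroid file is accepted at runtime through the same reader, keeping
  tests self-contained without redistributing it. ER status follows
  subtype (luminal ER+, basal-like 90% ER−, HER2 mixed) with at least one
  ER− entity guaranteed. Benign cell types carry 10-gene marker programs
  on non-panel genes.
- **Variant calls**: each caller emits each true variant with its
  sensitivity and adds Poisson-distributed spurious private calls.
  Depths are Poisson; alt counts are beta-binomial around the planted
  VAF (concentration 60), giving depth-dependent noise at the filter
  boundaries. Somatic truths default to normal VAF exactly 0 so that
  perfect caller profiles recover the planted set exactly; normal-sample
  noise is opt-in.
- **Peaks**: widths uniform on 200–1,500 bp, scores log-uniform, a
  configurable overlapping fraction, and deliberate chrY / N-gap
  plantings to exercise standardisation.
- **Motif matrices**: standard Gaussian deviations with stated shifts in
  stated groups.
- **Images**: duct rings (annuli) with configurable channel means and
  Gaussian noise, plus exact truth masks.

What the generators do **not** emulate: ambient RNA, doublets, batch
effects, gene-gene correlation beyond the subtype programs, mapping
artifacts, GC/length biases, or spatially correlated imaging noise.
Passing tests therefore demonstrate that the procedures compute what they
claim on data satisfying their assumptions — not that the thresholds are
optimal for any real cohort.

## Multiple testing and recovery limits

Bonferroni (`min(1, p·m)`) is used where the upstream convention is
family-wise control (DEG calling); BH step-up where it is FDR control
(motif tests, LOH). Both are validated against their closed-form
definitions. One structural consequence: an FDR-controlled caller admits
false discoveries at roughly the nominal rate per family, so *exact*
planted-set recovery is not a property BH-based calling can guarantee on
every seed — the motif filter is therefore evaluated on planted-TF
recovery and exclusion-rule correctness, with false extras reported as a
separate rate (≈ 0.1–0.2 TFs per run at q = 0.05 with 50 TFs). The
Bonferroni-based gene filter does achieve exact recovery.

## Problem sizes

Tests and the acceptance script run at deliberately compact sizes chosen
as the smallest at which each property is sharply testable: 60-entity
cohorts (20 seeds) for subtyping; 50 instances of 1,000 peaks for the
atlas oracle; exhaustive ±1 boundary grids (≈ 2,300 cells) for the
variant truth tables; 200 random 2×2 tables for the LOH closed form;
7 epithelial groups × 25 cells for lineage gene recovery; 6 groups × 60
cells × 50 TFs for motif recovery; 50 seeds × 40 TFs for null
calibration.
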