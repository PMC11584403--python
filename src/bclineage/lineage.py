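"""Lineage-of-origin marker calling by differential tests and set algebra.

The lineage hypothesis pairs each tumor subtype with its putative benign
cell of origin (basal-like tumor with luminal progenitor, LP; luminal A/B
tumor with mature luminal, LM) and asks which genes and TF motifs are
shared by a tumor and its progenitor but absent everywhere else in the
breast epithelium. Both the gene and the motif procedures are staged
filters: an inclusive differential test defines candidates, then
exclusion comparisons strip away cancer-generic and non-lineage signals.

Epithelial group labels used throughout: ``Basal_tumor``, ``Her2_tumor``,
``LumA_tumor``, ``LumB_tumor`` (or pooled ``Luminal_tumor`` for motifs),
``LP``, ``LM``, ``Basal_myoepithelial``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LineageComparisonSet",
    "SampleTumorDeg",
    "differential_expression",
    "differential_accessibility",
    "lineage_deg_filter",
    "differential_motif",
    "lineage_motif_filter",
    "subtype_specific_tfs",
    "surface_marker_call",
    "bonferroni",
]

BASAL_TUMOR = "Basal_tumor"
HER2_TUMOR = "Her2_tumor"
LUMA_TUMOR = "LumA_tumor"
LUMB_TUMOR = "LumB_tumor"
LUMINAL_TUMOR = "Luminal_tumor"
LP = "LP"
LM = "LM"
BASAL_MYO = "Basal_myoepithelial"

MOTIF_EPITHELIAL_GROUPS = (BASAL_TUMOR, HER2_TUMOR, LUMINAL_TUMOR, LM, LP, BASAL_MYO)


def bonferroni(p: np.ndarray) -> np.ndarray:
    """Family-wise adjustment: p * m, capped at 1."""
    return np.minimum(np.asarray(p, dtype=float) * len(p), 1.0)


def _pct_expressing(expr: pd.DataFrame, cells: list) -> pd.Series:
    return (expr[cells] > 0).mean(axis=1)


def _avg_log2fc(expr: pd.DataFrame, group_a: list, group_b: list) -> pd.Series:
    """Seurat-convention fold change on log1p-normalised values."""
    mean_a = np.expm1(expr[group_a]).mean(axis=1)
    mean_b = np.expm1(expr[group_b]).mean(axis=1)
    return np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)


def _logistic_lrt_p(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None
) -> float:
    """Likelihood-ratio p for a binomial GLM of group label on expression
    (plus covariates) against the covariates-only null."""
    import statsmodels.api as sm

    n = len(y)
    base = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    full = np.column_stack([base, x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit_null = sm.GLM(y, base, family=sm.families.Binomial()).fit(maxiter=100)
            fit_full = sm.GLM(y, full, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception:
            return 1.0
    lr = max(fit_null.deviance - fit_full.deviance, 0.0)
    return float(stats.chi2.sf(lr, df=1))


def differential_expression(
    expr: pd.DataFrame,
    group_a: list,
    group_b: list,
    test: str = "wilcoxon",
    *,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.0,
    only_pos: bool = False,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between two cell groups.

    ``expr`` is genes x cells of log1p-normalised expression. Genes are
    prefiltered: detected in at least ``min_pct`` of cells in one of the
    groups, and fold change clearing ``logfc_threshold`` (positive only
    when ``only_pos``). The surviving genes are tested (two-sided Wilcoxon
    rank-sum, or a binomial-GLM likelihood-ratio test with optional
    covariates) and Bonferroni-adjusted over the tested genes.

    Returns a DataFrame with columns gene, avg_log2fc, pct1, pct2
    (percentages), p, padj.
    """
    if test not in ("wilcoxon", "logistic_lrt"):
        raise ValueError(f"unknown test {test!r}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 cells")

    pct1 = _pct_expressing(expr, group_a)
    pct2 = _pct_expressing(expr, group_b)
    fc = _avg_log2fc(expr, group_a, group_b)

    tested = (np.maximum(pct1, pct2) >= min_pct)
    if only_pos:
        tested &= fc > logfc_threshold
    elif logfc_threshold > 0:
        tested &= fc.abs() >= logfc_threshold
    genes = expr.index[tested]

    cov = covariates.loc[group_a + group_b].to_numpy(dtype=float) if covariates is not None else None
    y = np.r_[np.ones(len(group_a)), np.zeros(len(group_b))]

    pvals = []
    a_mat = expr.loc[genes, group_a].to_numpy(dtype=float)
    b_mat = expr.loc[genes, group_b].to_numpy(dtype=float)
    for i in range(len(genes)):
        if test == "wilcoxon":
            a, b = a_mat[i], b_mat[i]
            if np.ptp(np.r_[a, b]) == 0:
                pvals.append(1.0)
            else:
                pvals.append(
                    float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")[1])
                )
        else:
            pvals.append(_logistic_lrt_p(y, np.r_[a_mat[i], b_mat[i]], cov))

    out = pd.DataFrame(
        {
            "gene": genes,
            "avg_log2fc": fc.loc[genes].to_numpy(),
            "pct1": pct1.loc[genes].to_numpy() * 100,
            "pct2": pct2.loc[genes].to_numpy() * 100,
            "p": pvals,
        }
    )
    out["padj"] = bonferroni(out["p"].to_numpy()) if len(out) else []
    return out


def differential_accessibility(
    peak_counts: pd.DataFrame,
    group_a: list,
    group_b: list,
    latent: pd.Series,
    *,
    min_pct: float = 0.1,
    min_diff_pct: float = 0.1,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differentially accessible peaks by logistic regression with the
    per-cell fraction of fragments in peaks as latent covariate.

    Prefilters: the peak is detected in at least ``min_pct`` of one group
    and the absolute difference of detection fractions is at least
    ``min_diff_pct``. Bonferroni adjustment over tested peaks; the
    ``significant`` column flags padj below ``padj_threshold``.
    """
    pct1 = _pct_expressing(peak_counts, group_a)
    pct2 = _pct_expressing(peak_counts, group_b)
    tested = (np.maximum(pct1, pct2) >= min_pct) & ((pct1 - pct2).abs() >= min_diff_pct)
    peaks_tested = peak_counts.index[tested]

    y = np.r_[np.ones(len(group_a)), np.zeros(len(group_b))]
    cov = latent.loc[group_a + group_b].to_numpy(dtype=float)[:, None]
    fc = _avg_log2fc(peak_counts, group_a, group_b)

    pvals = []
    a_mat = peak_counts.loc[peaks_tested, group_a].to_numpy(dtype=float)
    b_mat = peak_counts.loc[peaks_tested, group_b].to_numpy(dtype=float)
    for i in range(len(peaks_tested)):
        pvals.append(_logistic_lrt_p(y, np.r_[a_mat[i], b_mat[i]], cov))

    out = pd.DataFrame(
        {
            "peak": peaks_tested,
            "avg_log2fc": fc.loc[peaks_tested].to_numpy(),
            "pct1": pct1.loc[peaks_tested].to_numpy() * 100,
            "pct2": pct2.loc[peaks_tested].to_numpy() * 100,
            "p": pvals,
        }
    )
    out["padj"] = bonferroni(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["padj"] < padj_threshold
    return out


@dataclass
class LineageComparisonSet:
    """DEG tables for the staged lineage gene filter.

    G1: {basal-like tumor, LP} vs all other epithelial cells;
    G2: {LumA tumor, LumB tumor, LM} vs rest; G3: {LP, LM} vs rest
    (computed but not consumed by the default procedure);
    C1: basal-like tumor vs LP; C2: {LumA, LumB} tumor vs LM;
    A1: each epithelial cell type vs all other epithelial cells.

    Each table has at least columns ``gene`` and ``padj``.
    """

    G1: pd.DataFrame
    G2: pd.DataFrame
    C1: pd.DataFrame
    C2: pd.DataFrame
    A1: dict[str, pd.DataFrame]
    G3: pd.DataFrame | None = None

    def sig(self, name: str, padj_threshold: float = 0.05) -> set:
        table = getattr(self, name, None)
        if table is None:
            raise ValueError(f"missing comparison set {name!r}")
        return set(table.loc[table["padj"] < padj_threshold, "gene"])

    def sig_a1(self, cell_type: str, padj_threshold: float = 0.05) -> set:
        if cell_type not in self.A1:
            raise ValueError(f"missing A1 comparison for cell type {cell_type!r}")
        table = self.A1[cell_type]
        return set(table.loc[table["padj"] < padj_threshold, "gene"])


def lineage_deg_filter(
    cmp: LineageComparisonSet,
    lineage: str,
    expr_summaries: pd.DataFrame,
    *,
    padj_threshold: float = 0.05,
    min_pct_exp: float = 20.0,
    min_log2fc: float = 1.0,
    literal_text: bool = False,
) -> pd.DataFrame:
    """Staged set-algebra filter producing lineage-specific genes.

    Basal branch: start from significant G1 genes; remove genes in C1 or
    C2 (cancer-generic, not lineage); remove genes in G2 (luminal-
    transition); keep genes specific to basal tumor or LP in the
    one-vs-rest analysis (A1) and absent from the A1 sets of LumA/LumB/
    HER2 tumor, basal/myoepithelial and LM; finally require pct.exp > 20
    and avg_log2FC > 1 in ``expr_summaries`` (indexed by gene, columns
    ``pct_exp`` and ``avg_log2fc``). The luminal branch is symmetric
    (start from G2, exclude G1, A1 specificity to LumA/LumB tumor or LM);
    ``literal_text=True`` starts the luminal branch from G1 as well,
    reproducing a literal reading of the published description.

    Each survivor is labelled ``tumor-high``, ``progenitor-high`` or
    ``shared`` from its A1 provenance.
    """
    if lineage not in ("basal", "luminal"):
        raise ValueError(f"unknown lineage {lineage!r}")

    c1 = cmp.sig("C1", padj_threshold)
    c2 = cmp.sig("C2", padj_threshold)

    if lineage == "basal":
        start = cmp.sig("G1", padj_threshold)
        excluded_g = cmp.sig("G2", padj_threshold)
        tumor_a1 = cmp.sig_a1(BASAL_TUMOR, padj_threshold)
        progenitor_a1 = cmp.sig_a1(LP, padj_threshold)
        off_lineage = [LUMA_TUMOR, LUMB_TUMOR, HER2_TUMOR, BASAL_MYO, LM]
    else:
        start = cmp.sig("G1" if literal_text else "G2", padj_threshold)
        excluded_g = cmp.sig("G1", padj_threshold)
        tumor_a1 = cmp.sig_a1(LUMA_TUMOR, padj_threshold) | cmp.sig_a1(
            LUMB_TUMOR, padj_threshold
        )
        progenitor_a1 = cmp.sig_a1(LM, padj_threshold)
        off_lineage = [HER2_TUMOR, BASAL_MYO, BASAL_TUMOR]

    candidates = start - c1 - c2 - excluded_g
    candidates &= tumor_a1 | progenitor_a1
    for cell_type in off_lineage:
        candidates -= cmp.sig_a1(cell_type, padj_threshold)

    rows = []
    for gene in sorted(candidates):
        if gene not in expr_summaries.index:
            continue
        summary = expr_summaries.loc[gene]
        if not (summary["pct_exp"] > min_pct_exp and summary["avg_log2fc"] > min_log2fc):
            continue
        in_tumor = gene in tumor_a1
        in_prog = gene in progenitor_a1
        category = "shared" if (in_tumor and in_prog) else (
            "tumor-high" if in_tumor else "progenitor-high"
        )
        rows.append(
            {
                "gene": gene,
                "lineage": lineage,
                "category": category,
                "pct_exp": float(summary["pct_exp"]),
                "avg_log2fc": float(summary["avg_log2fc"]),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "lineage", "category", "pct_exp", "avg_log2fc"])


def differential_motif(
    motif_matrix: pd.DataFrame, group_a: list, group_b: list
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per TF motif with BH adjustment.

    ``motif_matrix`` is TFs x cells of bias-corrected deviation scores.
    The FDR family is the whole set of TFs in the assay. Returns columns
    tf, mean_a, mean_b, mean_diff, p, fdr.
    """
    a = motif_matrix[group_a].to_numpy(dtype=float)
    b = motif_matrix[group_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    pvals = np.empty(len(motif_matrix))
    for i in range(len(motif_matrix)):
        if np.ptp(np.r_[a[i], b[i]]) == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = stats.mannwhitneyu(
                a[i], b[i], alternative="two-sided", method="auto"
            )[1]
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "tf": motif_matrix.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "mean_diff": mean_a - mean_b,
            "p": pvals,
            "fdr": fdr,
        }
    )


def _enriched_tfs(
    motif_matrix: pd.DataFrame,
    group_a: list,
    group_b: list,
    fdr_threshold: float,
    min_diff: float = 0.0,
) -> set:
    """TFs significantly enriched (positive mean difference) in A vs B."""
    res = differential_motif(motif_matrix, group_a, group_b)
    if min_diff > 0:
        keep = (res["fdr"] < fdr_threshold) & (res["mean_diff"] >= min_diff)
    else:
        keep = (res["fdr"] < fdr_threshold) & (res["mean_diff"] > 0)
    return set(res.loc[keep, "tf"])


def lineage_motif_filter(
    motif_matrix: pd.DataFrame,
    groups: pd.Series,
    *,
    fdr_threshold: float = 0.05,
    nonlineage_min_diff: float = 0.5,
) -> dict[str, set]:
    """Staged filter producing basal- and luminal-lineage TF motif sets.

    Step 1 — for each lineage, test tumor + putative cell of origin
    ({basal tumor, LP} and {luminal tumor, LM}) against all other
    epithelial groups; keep TFs at FDR < 0.05 with positive mean motif
    score difference. Step 2 — exclude cancer-generic TFs enriched in
    BOTH luminal-tumor-vs-LM and basal-tumor-vs-LP. Step 3 — test every
    single group against all other epithelial cells and drop any
    candidate significantly enriched in a non-lineage group with mean
    difference of at least 0.5.

    ``groups`` maps each cell (column of ``motif_matrix``) to one of the
    six epithelial groups; all six must be present.
    """
    groups = groups.reindex(motif_matrix.columns)
    missing = set(MOTIF_EPITHELIAL_GROUPS) - set(groups.unique())
    if missing:
        raise ValueError(f"missing epithelial groups: {sorted(missing)}")
    members = {g: list(groups.index[groups == g]) for g in MOTIF_EPITHELIAL_GROUPS}

    def others(*included: str) -> list:
        return [c for g in MOTIF_EPITHELIAL_GROUPS if g not in included for c in members[g]]

    lineages = {
        "basal": (BASAL_TUMOR, LP),
        "luminal": (LUMINAL_TUMOR, LM),
    }
    candidates = {
        name: _enriched_tfs(
            motif_matrix, members[tumor] + members[origin], others(tumor, origin), fdr_threshold
        )
        for name, (tumor, origin) in lineages.items()
    }

    # step 2: cancer-associated, non-lineage TFs: enriched in both
    # tumor-vs-origin comparisons
    basal_vs_lp = _enriched_tfs(motif_matrix, members[BASAL_TUMOR], members[LP], fdr_threshold)
    luminal_vs_lm = _enriched_tfs(
        motif_matrix, members[LUMINAL_TUMOR], members[LM], fdr_threshold
    )
    shared = basal_vs_lp & luminal_vs_lm
    candidates = {k: v - shared for k, v in candidates.items()}

    # step 3: per-group one-vs-rest enrichment with a mean-difference floor
    per_group_enriched = {
        g: _enriched_tfs(
            motif_matrix, members[g], others(g), fdr_threshold, min_diff=nonlineage_min_diff
        )
        for g in MOTIF_EPITHELIAL_GROUPS
    }
    for name, (tumor, origin) in lineages.items():
        for g in MOTIF_EPITHELIAL_GROUPS:
            if g not in (tumor, origin):
                candidates[name] -= per_group_enriched[g]
    return candidates


def subtype_specific_tfs(
    motif_matrix: pd.DataFrame,
    groups: pd.Series,
    subtype_group: str,
    rna_fc: pd.Series,
    *,
    fdr_threshold: float = 0.05,
) -> set:
    """Subtype-specific TFs: enriched in one tumor subtype vs pooled other
    tumor cells, additionally requiring a positive RNA fold change for the
    TF gene in the same subtype-vs-rest comparison."""
    groups = groups.reindex(motif_matrix.columns)
    tumor_groups = [g for g in groups.unique() if str(g).endswith("_tumor")]
    if subtype_group not in tumor_groups:
        raise ValueError(f"{subtype_group!r} is not a tumor group in `groups`")
    cells_a = list(groups.index[groups == subtype_group])
    cells_b = [c for g in tumor_groups if g != subtype_group for c in groups.index[groups == g]]
    enriched = _enriched_tfs(motif_matrix, cells_a, cells_b, fdr_threshold)
    return {tf for tf in enriched if rna_fc.get(tf, 0.0) > 0}


@dataclass
class SampleTumorDeg:
    """One sample's tumor-vs-others DEG results for surface-marker calling.

    ``per_celltype`` maps each non-tumor cell type present in the sample
    to the tumor-vs-that-type DEG table; ``combined`` is tumor vs the
    pooled non-tumor population (None when the sample has no non-tumor
    cells). Tables carry columns gene, avg_log2fc, padj.
    """

    per_celltype: dict[str, pd.DataFrame] = field(default_factory=dict)
    combined: pd.DataFrame | None = None


def surface_marker_call(
    per_sample_deg: dict[str, SampleTumorDeg],
    surface_genes: set,
    *,
    min_higher_frac: float = 0.90,
    min_sig_frac: float = 0.75,
    padj_threshold: float = 0.05,
) -> list[str]:
    """Tumor cell-surface marker screen across a cohort of samples.

    A gene is a marker iff (1) in at least one sample its expression is
    higher in tumor cells than in EVERY other cell type present, with all
    pairwise differences significant (log fold change > 0, padj < 0.05);
    (2) tumor exceeds the combined non-tumor population in at least 90%
    of samples and significantly so in at least 75%; and (3) it is
    annotated as a cell-surface gene. Samples with no non-tumor cells are
    excluded from the denominators with a warning.
    """
    usable = {}
    for sample, deg in per_sample_deg.items():
        if deg.combined is None or not deg.per_celltype:
            warnings.warn(f"sample {sample!r} has no non-tumor cells; excluded", stacklevel=2)
            continue
        usable[sample] = deg
    if not usable:
        return []

    genes = sorted(
        set().union(*(set(d.combined["gene"]) for d in usable.values())) & surface_genes
    )
    n_samples = len(usable)

    markers = []
    for gene in genes:
        crit1 = False
        for deg in usable.values():
            ok = True
            for table in deg.per_celltype.values():
                row = table.loc[table["gene"] == gene]
                if row.empty or not (
                    (row["avg_log2fc"].iloc[0] > 0) and (row["padj"].iloc[0] < padj_threshold)
                ):
                    ok = False
                    break
            if ok:
                crit1 = True
                break
        if not crit1:
            continue

        n_higher = n_sig = 0
        for deg in usable.values():
            row = deg.combined.loc[deg.combined["gene"] == gene]
            if row.empty:
                continue
            if row["avg_log2fc"].iloc[0] > 0:
                n_higher += 1
                if row["padj"].iloc[0] < padj_threshold:
                    n_sig += 1
        if n_higher / n_samples >= min_higher_frac and n_sig / n_samples >= min_sig_frac:
            markers.append(gene)
    return markers
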