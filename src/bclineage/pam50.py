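"""PAM50 nearest-centroid intrinsic subtyping.

The classifier assigns each expression profile to the intrinsic subtype
(luminal A, luminal B, HER2-enriched, basal-like, normal-like) whose
centroid it correlates with best over the 50-gene panel, after per-gene
median centering. Because the cohort's ER+/ER- composition biases the
per-gene medians (and therefore the calls), bulk cohorts are subtyped by
a bootstrapped consensus: each iteration recomputes the medians from all
ER- samples plus an equal-size random subset of ER+ samples, centers the
whole cohort with those medians, and classifies every sample; the final
call is the subtype most commonly assigned across iterations.

Single-nucleus tumor data are too sparse for per-cell calls, so subtyping
is applied to cluster mean profiles, centered with a supplied median
vector, without bootstrapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PAM50_SUBTYPES",
    "PAM50Reference",
    "SubtypeCall",
    "fpkm_uq_normalize",
    "median_center",
    "classify_nearest_centroid",
    "bootstrap_consensus_subtype",
    "cluster_level_subtype",
    "read_centroid_file",
]

PAM50_SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal")

UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class PAM50Reference:
    """The 50-gene panel with per-subtype centroid profiles.

    ``centroids`` is genes x subtypes; ``medians`` (optional) is the
    per-gene reference median vector used for centering when no bootstrap
    is performed.
    """

    centroids: pd.DataFrame
    medians: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != 50:
            raise ValueError(
                f"PAM50 reference must cover exactly 50 genes, got "
                f"{self.centroids.shape[0]}"
            )
        if self.centroids.columns.duplicated().any():
            raise ValueError("duplicate subtype names in centroid table")
        if self.centroids.isna().any().any():
            raise ValueError("centroid table has missing values")
        if self.medians is not None and not self.medians.index.equals(
            self.centroids.index
        ):
            raise ValueError("median vector does not cover the centroid genes")

    @property
    def genes(self) -> pd.Index:
        return self.centroids.index

    @property
    def subtypes(self) -> tuple[str, ...]:
        return tuple(self.centroids.columns)


@dataclass
class SubtypeCall:
    """Consensus subtype for one entity with its per-iteration votes."""

    entity: str
    final: str
    vote_fractions: dict[str, float]
    calls: list[str] = field(default_factory=list)
    mean_correlations: dict[str, float] = field(default_factory=dict)


def read_centroid_file(path) -> PAM50Reference:
    """Read a centroid TSV: first column gene id, one column per subtype.

    Accepts both the package's own format and the published Parker-style
    file (which carries the same layout with a header row).
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    table = table.select_dtypes(include=[np.number])
    return PAM50Reference(centroids=table)


def fpkm_uq_normalize(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    protein_coding: pd.Index | None = None,
) -> pd.DataFrame:
    """Upper-quartile FPKM with log2(x+1) transform.

    value = count * 1e9 / (U * L) where U is the 75th percentile of the
    sample's nonzero protein-coding counts and L the gene length in bases;
    the result is log2 transformed with one pseudocount.

    Parameters
    ----------
    counts
        Raw counts, genes x samples.
    gene_lengths
        Length in bases per gene; must cover every gene in ``counts``.
    protein_coding
        Genes entering the upper-quartile computation; defaults to all.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"gene_lengths missing {len(missing)} genes, e.g. {missing[0]!r}")
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")

    uq_genes = counts.index if protein_coding is None else counts.index.intersection(protein_coding)
    out = {}
    for sample in counts.columns:
        col = counts[sample].astype(float)
        nonzero = col.loc[uq_genes]
        nonzero = nonzero[nonzero > 0]
        if nonzero.empty:
            raise ValueError(f"sample {sample!r} has no nonzero counts: upper quartile undefined")
        u = float(np.percentile(nonzero.to_numpy(), 75))
        if u == 0:
            raise ValueError(f"sample {sample!r} has zero upper-quartile count")
        out[sample] = col * 1e9 / (u * lengths)
    fpkm_uq = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return np.log2(fpkm_uq + 1.0)


def median_center(expr: pd.DataFrame, medians: pd.Series) -> pd.DataFrame:
    """Subtract a per-gene median from each panel gene's row.

    Genes of ``expr`` absent from ``medians`` are dropped with a warning;
    the result is restricted to (and ordered by) the median vector's genes
    present in ``expr``.
    """
    extra = expr.index.difference(medians.index)
    if len(extra):
        warnings.warn(
            f"dropping {len(extra)} non-panel genes from expression matrix",
            stacklevel=2,
        )
    genes = medians.index.intersection(expr.index)
    return expr.loc[genes].sub(medians.loc[genes], axis=0)


def _correlations(profile: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    """Correlation of one profile against each centroid column."""
    if metric == "spearman":
        profile = stats.rankdata(profile)
        centroids = np.apply_along_axis(stats.rankdata, 0, centroids)
    p = profile - profile.mean()
    c = centroids - centroids.mean(axis=0)
    denom = np.sqrt((p**2).sum() * (c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (p @ c) / denom


def classify_nearest_centroid(
    profile: pd.Series, ref: PAM50Reference, metric: str = "spearman"
) -> tuple[str, dict[str, float]]:
    """Assign the argmax-correlation subtype for one 50-gene profile.

    Returns ``(subtype, correlations)``. A constant (zero-variance)
    profile is explicitly ``"unclassifiable"`` with NaN correlations
    rather than an arbitrary subtype.
    """
    if metric not in ("spearman", "pearson"):
        raise ValueError(f"unknown metric {metric!r}")
    aligned = profile.loc[ref.genes].to_numpy(dtype=float)
    if np.isnan(aligned).any():
        raise ValueError("profile does not cover all 50 panel genes")
    corr = _correlations(aligned, ref.centroids.to_numpy(dtype=float), metric)
    cors = dict(zip(ref.subtypes, (float(x) for x in corr)))
    if np.ptp(aligned) == 0 or np.isnan(corr).all():
        return UNCLASSIFIABLE, {s: float("nan") for s in ref.subtypes}
    best = int(np.nanargmax(corr))
    return ref.subtypes[best], cors


def _classify_matrix(
    centered: pd.DataFrame, ref: PAM50Reference, metric: str
) -> tuple[list[str], np.ndarray]:
    """Classify every column of a centered panel matrix; vectorised."""
    x = centered.loc[ref.genes].to_numpy(dtype=float)
    cent = ref.centroids.to_numpy(dtype=float)
    if metric == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
        cent = np.apply_along_axis(stats.rankdata, 0, cent)
    xc = x - x.mean(axis=0)
    cc = cent - cent.mean(axis=0)
    xn = np.sqrt((xc**2).sum(axis=0))
    cn = np.sqrt((cc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc.T @ cc) / np.outer(xn, cn)  # entities x subtypes
    calls = []
    for i in range(corr.shape[0]):
        row = corr[i]
        if np.isnan(row).all() or xn[i] == 0:
            calls.append(UNCLASSIFIABLE)
        else:
            calls.append(ref.subtypes[int(np.nanargmax(row))])
    return calls, corr


def bootstrap_consensus_subtype(
    expr: pd.DataFrame,
    er_status: pd.Series,
    ref: PAM50Reference,
    n_iter: int = 1000,
    seed: int | None = None,
    metric: str = "spearman",
) -> dict[str, SubtypeCall]:
    """ER-balanced bootstrapped consensus PAM50 calls for a bulk cohort.

    Each iteration draws all ER- entities plus an equal-size uniform
    random subset (without replacement) of ER+ entities, computes per-gene
    medians over that subset, median-centers the full cohort with them and
    classifies every entity. The final call per entity is the modal
    subtype across iterations; ties are broken by the higher mean
    correlation rank across iterations.

    Parameters
    ----------
    expr
        Normalised expression, genes x entities; must cover the panel.
    er_status
        Entity -> {"pos", "neg"}; at least one "neg" entity is required.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    bad = set(er_status.unique()) - {"pos", "neg"}
    if bad:
        raise ValueError(f"unknown ER status values: {sorted(bad)}")
    entities = list(expr.columns)
    er = er_status.reindex(entities)
    if er.isna().any():
        raise ValueError("er_status missing for some entities")
    neg = [e for e in entities if er[e] == "neg"]
    pos = [e for e in entities if er[e] == "pos"]
    if not neg:
        raise ValueError(
            "no ER- entities: balanced bootstrap undefined; center with plain "
            "cohort medians and classify once instead"
        )

    panel = expr.loc[ref.genes]
    if panel.isna().any().any():
        raise ValueError("expression matrix does not cover all 50 panel genes")

    rng = np.random.default_rng(seed)
    n_draw = min(len(neg), len(pos))
    calls_per_iter: list[list[str]] = []
    corr_sum = np.zeros((len(entities), len(ref.subtypes)))
    for _ in range(n_iter):
        drawn = list(rng.choice(pos, size=n_draw, replace=False)) if pos else []
        subset = panel[neg + drawn]
        medians = subset.median(axis=1)
        centered = panel.sub(medians, axis=0)
        calls, corr = _classify_matrix(centered, ref, metric)
        calls_per_iter.append(calls)
        corr_sum += np.nan_to_num(corr)

    mean_corr = corr_sum / n_iter
    results: dict[str, SubtypeCall] = {}
    for i, entity in enumerate(entities):
        votes = pd.Series([calls[i] for calls in calls_per_iter]).value_counts()
        fractions = (votes / n_iter).to_dict()
        top = votes.max()
        tied = sorted(votes[votes == top].index)
        if len(tied) == 1:
            final = tied[0]
        else:
            # deterministic tie-break: highest mean correlation across iterations
            by_corr = {
                s: mean_corr[i, ref.subtypes.index(s)] if s in ref.subtypes else -np.inf
                for s in tied
            }
            final = max(sorted(tied), key=lambda s: by_corr[s])
        results[entity] = SubtypeCall(
            entity=entity,
            final=final,
            vote_fractions=fractions,
            calls=[calls[i] for calls in calls_per_iter],
            mean_correlations=dict(zip(ref.subtypes, mean_corr[i])),
        )
    return results


def cluster_level_subtype(
    tumor_expr: pd.DataFrame,
    clusters: pd.Series,
    ref: PAM50Reference,
    medians: pd.Series,
    metric: str = "spearman",
) -> dict[str, str]:
    """Single-pass subtype per tumor cluster from cluster mean profiles.

    Mean expression of the 50 panel genes is computed per cluster,
    median-centered with the supplied medians, and classified once (no
    bootstrap). Raises on an empty cluster label.
    """
    clusters = clusters.reindex(tumor_expr.columns)
    if clusters.isna().any():
        raise ValueError("cluster labels missing for some cells")
    out: dict[str, str] = {}
    for cluster, members in clusters.groupby(clusters).groups.items():
        if len(members) == 0:
            raise ValueError(f"cluster {cluster!r} is empty")
        mean_profile = tumor_expr.loc[ref.genes, list(members)].mean(axis=1)
        centered = mean_profile - medians.loc[ref.genes]
        subtype, _ = classify_nearest_centroid(centered, ref, metric=metric)
        out[str(cluster)] = subtype
    return out
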