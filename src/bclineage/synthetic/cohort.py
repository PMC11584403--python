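"""Subtype-structured expression cohorts with a matching centroid panel.

Counts are negative-binomial with log-linear means: each tumor entity's
panel-gene log2 mean profile is a shared baseline plus its subtype's
centroid scaled by ``effect_size``; the NB dispersion sets the
overdispersion observed in real bulk/single-nucleus assays without
modelling ambient RNA. Benign duct cell types (LP, LM,
basal/myoepithelial) carry distinct marker programs on non-panel genes.
The drawn centroids and the cohort per-gene median vector are emitted as
a synthetic centroid reference so the subtyper can be exercised without
the published centroid file (the real file is accepted at runtime through
the same reader).

ER status is generated consistently with subtype: luminal entities are
ER+, basal-like mostly ER-, HER2-enriched mixed; at least one ER- entity
is guaranteed so the ER-balanced bootstrap is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bclineage.lineage import BASAL_MYO, LM, LP
from bclineage.pam50 import PAM50_SUBTYPES, PAM50Reference
from bclineage.synthetic.truth import PlantedTruth

__all__ = ["CohortSpec", "ExpressionCohort", "generate_expression_cohort", "BENIGN_CELL_TYPES"]

BENIGN_CELL_TYPES = (LP, LM, BASAL_MYO)
_MARKERS_PER_TYPE = 10


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic expression cohort."""

    n_samples: int
    subtype_mix: dict[str, int]
    cells_per_sample: int = 1
    n_genes: int = 200
    panel_size: int = 50
    effect_size: float = 5.0
    noise_dispersion: float = 0.15
    benign_per_sample: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.cells_per_sample <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.panel_size > self.n_genes:
            raise ValueError("panel_size must not exceed n_genes")
        if self.effect_size < 0 or self.noise_dispersion <= 0:
            raise ValueError("effect_size must be >= 0 and noise_dispersion > 0")
        unknown = set(self.subtype_mix) - set(PAM50_SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtypes in subtype_mix: {sorted(unknown)}")
        if any(v <= 0 for v in self.subtype_mix.values()):
            raise ValueError("subtype_mix counts must be positive")
        if sum(self.subtype_mix.values()) != self.n_samples:
            raise ValueError("subtype_mix must sum to n_samples")


@dataclass
class ExpressionCohort:
    """Gene x entity counts with log-normalised values and annotations."""

    counts: pd.DataFrame
    lognorm: pd.DataFrame
    obs: pd.DataFrame = field(repr=False)

    @property
    def entities(self) -> pd.Index:
        return self.counts.columns


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2."""
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    return np.log2(counts.div(totals, axis=1) * scale + 1.0)


def generate_expression_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionCohort, PAM50Reference, PlantedTruth]:
    """Generate a cohort of tumor (and optionally benign) entities.

    Returns the cohort, a synthetic centroid reference (centroids plus the
    cohort per-gene median vector over tumor entities), and the planted
    truth (per-entity subtype / cell type / ER status).
    """
    rng = np.random.default_rng(spec.seed)

    panel_genes = [f"PAM50_{i + 1:02d}" for i in range(spec.panel_size)]
    other_genes = [f"GENE_{i + 1:04d}" for i in range(spec.n_genes - spec.panel_size)]
    genes = panel_genes + other_genes

    centroids = pd.DataFrame(
        rng.normal(size=(spec.panel_size, len(PAM50_SUBTYPES))),
        index=panel_genes,
        columns=list(PAM50_SUBTYPES),
    )
    baseline = pd.Series(rng.uniform(3.0, 7.0, size=len(genes)), index=genes)

    # benign marker programs live on non-panel genes
    marker_genes: dict[str, list[str]] = {}
    pool = list(other_genes)
    for cell_type in BENIGN_CELL_TYPES:
        take = min(_MARKERS_PER_TYPE, len(pool))
        marker_genes[cell_type] = pool[:take]
        pool = pool[take:]

    sample_subtypes: list[str] = []
    for subtype in PAM50_SUBTYPES:
        sample_subtypes.extend([subtype] * spec.subtype_mix.get(subtype, 0))

    columns: list[str] = []
    mus: list[np.ndarray] = []
    obs_rows: list[dict] = []
    truth = PlantedTruth()

    er_by_sample: dict[str, str] = {}
    for s_idx, subtype in enumerate(sample_subtypes):
        sample = f"S{s_idx + 1:03d}"
        if subtype in ("LumA", "LumB", "Normal"):
            er = "pos"
        elif subtype == "Basal":
            er = "neg" if rng.random() < 0.9 else "pos"
        else:  # Her2: mixed
            er = "neg" if rng.random() < 0.5 else "pos"
        er_by_sample[sample] = er

        for c_idx in range(spec.cells_per_sample):
            entity = sample if spec.cells_per_sample == 1 else f"{sample}_T{c_idx + 1:03d}"
            logmu = baseline.copy()
            logmu.loc[panel_genes] += spec.effect_size * centroids[subtype]
            mus.append(np.power(2.0, logmu.to_numpy()))
            columns.append(entity)
            obs_rows.append(
                {"entity": entity, "sample": sample, "cell_type": "tumor",
                 "subtype": subtype, "er_status": er}
            )
            truth.entity_subtype[entity] = subtype
            truth.entity_cell_type[entity] = "tumor"
            truth.er_status[entity] = er

        for b_idx in range(spec.benign_per_sample):
            cell_type = BENIGN_CELL_TYPES[b_idx % len(BENIGN_CELL_TYPES)]
            entity = f"{sample}_B{b_idx + 1:03d}"
            logmu = baseline.copy()
            logmu.loc[marker_genes[cell_type]] += spec.effect_size
            mus.append(np.power(2.0, logmu.to_numpy()))
            columns.append(entity)
            obs_rows.append(
                {"entity": entity, "sample": sample, "cell_type": cell_type,
                 "subtype": "", "er_status": er}
            )
            truth.entity_cell_type[entity] = cell_type

    # the balanced bootstrap needs at least one ER- entity
    if "neg" not in er_by_sample.values():
        last = list(er_by_sample)[-1]
        er_by_sample[last] = "neg"
        for row in obs_rows:
            if row["sample"] == last:
                row["er_status"] = "neg"
                truth.er_status[row["entity"]] = "neg"

    mu_matrix = np.column_stack(mus)
    counts = pd.DataFrame(
        _nb_counts(rng, mu_matrix, spec.noise_dispersion),
        index=genes,
        columns=columns,
    )
    lognorm = _log_normalize(counts)
    obs = pd.DataFrame(obs_rows).set_index("entity")

    tumor_entities = obs.index[obs["cell_type"] == "tumor"]
    medians = lognorm.loc[panel_genes, tumor_entities].median(axis=1)
    ref = PAM50Reference(centroids=centroids, medians=medians)

    truth.lineage_genes = {ct: list(gs) for ct, gs in marker_genes.items()}
    cohort = ExpressionCohort(counts=counts, lognorm=lognorm, obs=obs)
    return cohort, ref, truth
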