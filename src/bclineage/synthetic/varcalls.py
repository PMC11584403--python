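"""Multi-caller variant call sets around planted true variants.

Each caller emits every true variant independently with its sensitivity
and adds spurious private calls at its false-call rate. Depths are
Poisson around the configured means; alt counts are beta-binomial around
the planted VAF, giving realistic depth-dependent noise at the filter
boundaries. Normal-sample VAFs for somatic truths sit near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from bclineage.variants import VariantRecord

__all__ = ["TrueVariant", "CallerProfile", "generate_caller_calls"]


@dataclass(frozen=True)
class TrueVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_vaf: float = 0.4
    normal_vaf: float = 0.0
    exonic: bool = True
    in_dbsnp: bool = False
    in_cosmic: bool = False
    gnomad_af: float | None = None

    def as_dict(self) -> dict:
        return {
            "chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt,
            "tumor_vaf": self.tumor_vaf,
        }


@dataclass(frozen=True)
class CallerProfile:
    """Per-caller emission model.

    ``false_call_rate`` is the expected number of spurious private calls
    (Poisson mean) the caller adds to the set.
    """

    name: str
    sensitivity: float = 1.0
    false_call_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.false_call_rate < 0:
            raise ValueError("false_call_rate must be nonnegative")


def _betabinom_alt(
    rng: np.random.Generator, depth: int, vaf: float, concentration: float = 60.0
) -> int:
    if depth == 0:
        return 0
    if vaf <= 0:
        return 0
    if vaf >= 1:
        return depth
    a = vaf * concentration
    b = (1 - vaf) * concentration
    return int(stats.betabinom.rvs(depth, a, b, random_state=rng))


def generate_caller_calls(
    true_variants: list[TrueVariant],
    caller_profiles: list[CallerProfile],
    seed: int,
    *,
    mean_tumor_depth: float = 60.0,
    mean_normal_depth: float = 40.0,
    normal_error_rate: float = 0.0,
) -> list[VariantRecord]:
    """Emit per-caller variant records around the planted truth."""
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    for profile in caller_profiles:
        for tv in true_variants:
            if rng.random() > profile.sensitivity:
                continue
            t_depth = max(1, int(rng.poisson(mean_tumor_depth)))
            n_depth = max(1, int(rng.poisson(mean_normal_depth)))
            t_alt = _betabinom_alt(rng, t_depth, tv.tumor_vaf)
            p_normal = min(1.0, tv.normal_vaf + normal_error_rate)
            n_alt = (
                _betabinom_alt(rng, n_depth, tv.normal_vaf)
                if tv.normal_vaf > 0
                else int(rng.binomial(n_depth, p_normal))
            )
            records.append(
                VariantRecord(
                    chrom=tv.chrom, pos=tv.pos, ref=tv.ref, alt=tv.alt,
                    caller=profile.name,
                    tumor_depth=t_depth, tumor_alt=t_alt,
                    normal_depth=n_depth, normal_alt=n_alt,
                    exonic=tv.exonic, in_dbsnp=tv.in_dbsnp, in_cosmic=tv.in_cosmic,
                    gnomad_af=tv.gnomad_af,
                )
            )
        n_spurious = int(rng.poisson(profile.false_call_rate))
        for _ in range(n_spurious):
            t_depth = max(1, int(rng.poisson(mean_tumor_depth)))
            n_depth = max(1, int(rng.poisson(mean_normal_depth)))
            vaf = float(rng.uniform(0.05, 0.4))
            ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            records.append(
                VariantRecord(
                    chrom=f"chr{int(rng.integers(1, 23))}",
                    pos=int(rng.integers(1, 5_000_000)),
                    ref=ref,
                    alt=alt,
                    caller=profile.name,
                    tumor_depth=t_depth,
                    tumor_alt=_betabinom_alt(rng, t_depth, vaf),
                    normal_depth=n_depth,
                    normal_alt=int(rng.binomial(n_depth, normal_error_rate)),
                    exonic=bool(rng.random() < 0.8),
                    in_dbsnp=bool(rng.random() < 0.2),
                    in_cosmic=bool(rng.random() < 0.1),
                )
            )
    return records
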