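"""Diapause phenotyping and extreme-phenotype bulk formation.

Diapause incidence (DI) is the proportion of a female's eggs that enter
developmental arrest under a short-day photoperiod.  DI is modelled on the
liability scale: expected DI = logistic(intercept + sum(effect * TEMP-ancestry
dosage at each QTL) + noise), and the observed DI is a binomial draw over the
female's egg count.  The optional Gaussian liability noise (``liability_sd``)
stands in for unmodelled genetic and environmental variance; without it a
QTL-free line would produce no phenotypic spread beyond egg-count sampling
noise and the extreme bulks could never fill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from bsakit.sim.breeding import SimIndividual
from bsakit.sim.founders import QtlLocus

logger = logging.getLogger(__name__)


@dataclass
class PhenotypedFemale:
    individual: SimIndividual
    egg_count: int
    di_observed: float  # proportion of diapause eggs
    di_expected: float
    bulk_class: str = "none"  # 'low', 'high' or 'none'


@dataclass(frozen=True)
class BulkSpec:
    """Bulk-assignment rule for one intercross line.

    The study thresholds: low bulk DI <= 10% (line 1) or <= 5% (line 2),
    high bulk DI >= 50% for both; bulk sizes 11/11 (line 1) and 12/8 (line 2).
    """

    line_id: int
    low_threshold: float
    high_threshold: float = 0.50
    low_target: int | None = None
    high_target: int | None = None

    def __post_init__(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be below high_threshold")

    @classmethod
    def line1(cls) -> "BulkSpec":
        return cls(line_id=1, low_threshold=0.10, low_target=11, high_target=11)

    @classmethod
    def line2(cls) -> "BulkSpec":
        return cls(line_id=2, low_threshold=0.05, low_target=12, high_target=8)


@dataclass
class Bulks:
    line_id: int
    low: list[PhenotypedFemale]
    high: list[PhenotypedFemale]
    flags: list[str] = field(default_factory=list)


def assign_phenotypes(
    females: list[SimIndividual],
    qtls: list[QtlLocus],
    rng: np.random.Generator,
    intercept: float = 0.0,
    liability_sd: float = 0.0,
    egg_range: tuple[int, int] = (20, 69),
) -> list[PhenotypedFemale]:
    """Phenotype each female: egg count, expected and observed DI.

    An empty QTL list is a pure null; negative effects are allowed.
    """
    lo, hi = egg_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid egg range {egg_range}")
    out = []
    for ind in females:
        liability = intercept
        for q in qtls:
            liability += q.effect * ind.temp_dosage_at(q.chrom, q.pos)
        if liability_sd > 0:
            liability += rng.normal(0.0, liability_sd)
        p = float(expit(liability))
        eggs = int(rng.integers(lo, hi + 1))
        observed = rng.binomial(eggs, p) / eggs
        out.append(
            PhenotypedFemale(
                individual=ind,
                egg_count=eggs,
                di_observed=float(observed),
                di_expected=p,
            )
        )
    return out


def form_bulks(phenotyped: list[PhenotypedFemale], spec: BulkSpec) -> Bulks:
    """Assign females to low/high bulks by DI thresholds (boundary inclusive).

    If more females qualify than the target bulk size, the most extreme DIs
    are kept.  Empty bulks are flagged and logged, not fatal.
    """
    if not phenotyped:
        raise ValueError("no phenotyped females")
    low = sorted(
        (f for f in phenotyped if f.di_observed <= spec.low_threshold),
        key=lambda f: f.di_observed,
    )
    high = sorted(
        (f for f in phenotyped if f.di_observed >= spec.high_threshold),
        key=lambda f: -f.di_observed,
    )
    if spec.low_target is not None:
        low = low[: spec.low_target]
    if spec.high_target is not None:
        high = high[: spec.high_target]
    for f in phenotyped:
        f.bulk_class = "none"
    for f in low:
        f.bulk_class = "low"
    for f in high:
        f.bulk_class = "high"
    flags = []
    for name, bulk in (("low", low), ("high", high)):
        if not bulk:
            flags.append(f"empty_{name}_bulk")
            logger.warning("line %d: %s bulk is empty", spec.line_id, name)
    return Bulks(line_id=spec.line_id, low=low, high=high, flags=flags)
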