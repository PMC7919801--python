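"""Meiosis with a Poisson crossover model and founder-origin bookkeeping.

Each chromosome of each simulated individual is an :class:`AncestryHaplotype`:
an ordered partition of [1, L] into segments labelled by the founder haplotype
(0/1 = the two haplotypes of the F0 TEMP female, 2/3 = the F0 TROP male) they
descend from.  Crossovers per meiosis are Poisson with mean cM/100 under a
linear genetic <-> physical map, with no interference and no obligate chiasma.

Besides the segment structure each haplotype carries
``lineage_crossovers``: the expected number of crossover events accumulated
along the meiotic lineage that produced it (the new meiosis' drawn count plus
the average of the two parental haplotypes' accumulated counts).  An F_k
transmitted gamete accumulates k-1 meioses, which is what makes the apparent
genetic map of an advanced intercross expand by a factor of k-1 relative
to an F2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bsakit.layout import Chromosome, ConfigurationError, GenomeLayout


@dataclass
class AncestryHaplotype:
    """One chromosome copy as founder-origin segments.

    ``starts[i]`` is the 1-based first bp of segment i; segment i ends at
    ``starts[i+1] - 1`` (the last segment ends at ``length``).  ``founders``
    holds the founder haplotype id of each segment.
    """

    chrom: str
    length: int
    starts: np.ndarray  # int64, starts[0] == 1, strictly increasing
    founders: np.ndarray  # int8 founder haplotype ids
    lineage_crossovers: float = 0.0
    n_meiotic_crossovers: int = 0  # crossovers drawn in the meiosis creating this

    @classmethod
    def founder(cls, chrom: str, length: int, founder_id: int) -> "AncestryHaplotype":
        return cls(
            chrom=chrom,
            length=length,
            starts=np.array([1], dtype=np.int64),
            founders=np.array([founder_id], dtype=np.int8),
        )

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    def segments(self) -> list[tuple[int, int, int]]:
        """Segments as (start, end, founder_id), 1-based inclusive."""
        ends = np.append(self.starts[1:] - 1, self.length)
        return [
            (int(s), int(e), int(f))
            for s, e, f in zip(self.starts, ends, self.founders)
        ]

    def founder_at(self, positions: np.ndarray) -> np.ndarray:
        """Founder haplotype id at each 1-based bp position (vectorized)."""
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        return self.founders[idx]

    def validate(self) -> None:
        """Assert the segments partition [1, length] without gaps or overlaps."""
        if self.starts[0] != 1:
            raise AssertionError(f"{self.chrom}: first segment starts at {self.starts[0]}")
        if len(self.starts) != len(self.founders):
            raise AssertionError("starts/founders length mismatch")
        if np.any(np.diff(self.starts) <= 0):
            raise AssertionError("segment starts not strictly increasing")
        if self.starts[-1] > self.length:
            raise AssertionError("segment start beyond chromosome end")
        # adjacent segments with identical founders are allowed but normalized away
        if np.any(np.diff(self.founders.astype(int)) == 0):
            raise AssertionError("adjacent segments share a founder id (not merged)")


def _merge_runs(starts: np.ndarray, founders: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero-length segments and merge adjacent same-founder runs."""
    keep = np.ones(len(starts), dtype=bool)
    if len(starts) > 1:
        keep[1:] = founders[1:] != founders[:-1]
    return starts[keep], founders[keep]


def meiosis(
    hap_a: AncestryHaplotype,
    hap_b: AncestryHaplotype,
    chrom: Chromosome,
    rng: np.random.Generator,
) -> AncestryHaplotype:
    """Recombine two parental haplotypes of one chromosome into a gamete.

    The crossover count is Poisson(genetic_length / 100); crossover positions
    are uniform in genetic-map coordinate (hence, under the linear map,
    uniform in bp); the source haplotype alternates between crossovers
    starting from a fair-coin choice.
    """
    if hap_a.chrom != hap_b.chrom or hap_a.length != hap_b.length:
        raise ConfigurationError("parental haplotypes belong to different chromosomes")
    n_xo = rng.poisson(chrom.genetic_length / 100.0)
    lineage = 0.5 * (hap_a.lineage_crossovers + hap_b.lineage_crossovers) + n_xo
    current, other = (hap_a, hap_b) if rng.random() < 0.5 else (hap_b, hap_a)
    if n_xo == 0:
        out = AncestryHaplotype(
            chrom=current.chrom,
            length=current.length,
            starts=current.starts.copy(),
            founders=current.founders.copy(),
            lineage_crossovers=lineage,
            n_meiotic_crossovers=0,
        )
        return out

    # crossover after bp position x: [.. x] from current source, (x ..] from other
    xo_cm = np.sort(rng.uniform(0.0, chrom.genetic_length, size=n_xo))
    xo_bp = np.unique(
        np.clip(
            np.round(xo_cm / chrom.genetic_length * chrom.physical_length),
            1,
            chrom.physical_length - 1,
        ).astype(np.int64)
    )
    bounds = np.concatenate(([0], xo_bp, [chrom.physical_length]))
    sources = (hap_a, hap_b)
    first = 0 if current is hap_a else 1
    starts_parts: list[np.ndarray] = []
    founders_parts: list[np.ndarray] = []
    for i in range(len(bounds) - 1):
        lo, hi = int(bounds[i]) + 1, int(bounds[i + 1])  # 1-based inclusive block
        src = sources[(first + i) % 2]
        j0 = np.searchsorted(src.starts, lo, side="right") - 1
        j1 = np.searchsorted(src.starts, hi, side="right")
        seg_starts = src.starts[j0:j1].copy()
        seg_starts[0] = lo
        starts_parts.append(seg_starts)
        founders_parts.append(src.founders[j0:j1])
    starts = np.concatenate(starts_parts)
    founders = np.concatenate(founders_parts)
    starts, founders = _merge_runs(starts, founders)
    return AncestryHaplotype(
        chrom=chrom.id,
        length=chrom.physical_length,
        starts=starts,
        founders=founders,
        lineage_crossovers=lineage,
        n_meiotic_crossovers=int(len(xo_bp)),
    )


def make_gamete(
    parent: "SimIndividual",
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> dict[str, AncestryHaplotype]:
    """One gamete: an independent meiosis on every chromosome of ``parent``.

    Gametes made by the F0 founders start the lineage-crossover counter at
    zero: crossovers in an F0 meiosis recombine a founder's own two
    haplotypes and are invisible to the TEMP x TROP map, so accumulation
    begins with the F1 meiosis (an F_k transmitted gamete then carries k - 1
    rounds of map-relevant recombination).
    """
    gamete = {}
    for chrom in layout:
        hap_a, hap_b = parent.haplotypes[chrom.id]
        hap = meiosis(hap_a, hap_b, chrom, rng)
        if parent.generation == 0:
            hap.lineage_crossovers = 0.0
        gamete[chrom.id] = hap
    return gamete
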