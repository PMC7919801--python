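"""Intercross breeding: founders, random within-line mating, genotypes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bsakit.layout import ConfigurationError, GenomeLayout
from bsakit.sim.founders import FounderModel, TEMP_FOUNDER_HAPS, TROP_FOUNDER_HAPS
from bsakit.sim.meiosis import AncestryHaplotype, make_gamete


@dataclass
class SimIndividual:
    """One mosquito: a generation label, sex, and two haplotypes per chromosome."""

    generation: int  # 0 for F0, k for F_k
    sex: str  # 'F' or 'M'
    haplotypes: dict[str, tuple[AncestryHaplotype, AncestryHaplotype]]

    @property
    def label(self) -> str:
        return f"F{self.generation}"

    def temp_dosage_at(self, chrom: str, pos: int) -> int:
        """Number of haplotypes (0..2) with TEMP-founder ancestry at a locus."""
        p = np.array([pos], dtype=np.int64)
        return sum(
            int(h.founder_at(p)[0] in TEMP_FOUNDER_HAPS)
            for h in self.haplotypes[chrom]
        )


def founder_pair(layout: GenomeLayout) -> tuple[SimIndividual, SimIndividual]:
    """The F0 TEMP female (founder haplotypes 0, 1) and TROP male (2, 3)."""
    def build(sex: str, hap_ids: tuple[int, int]) -> SimIndividual:
        haps = {
            c.id: (
                AncestryHaplotype.founder(c.id, c.physical_length, hap_ids[0]),
                AncestryHaplotype.founder(c.id, c.physical_length, hap_ids[1]),
            )
            for c in layout
        }
        return SimIndividual(generation=0, sex=sex, haplotypes=haps)

    return build("F", TEMP_FOUNDER_HAPS), build("M", TROP_FOUNDER_HAPS)


def _offspring(
    mother: SimIndividual,
    father: SimIndividual,
    layout: GenomeLayout,
    generation: int,
    sex: str,
    rng: np.random.Generator,
) -> SimIndividual:
    egg = make_gamete(mother, layout, rng)
    sperm = make_gamete(father, layout, rng)
    haps = {c.id: (egg[c.id], sperm[c.id]) for c in layout}
    return SimIndividual(generation=generation, sex=sex, haplotypes=haps)


def _sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random sexes, guaranteed to include both when n >= 2."""
    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    if n >= 2 and len(set(sexes)) == 1:
        sexes[rng.integers(n)] = "F" if sexes[0] == "M" else "M"
    return sexes


def breed_intercross(
    layout: GenomeLayout,
    founders: tuple[SimIndividual, SimIndividual],
    generations: int,
    pop_size: int,
    rng: np.random.Generator,
    final_size: int | None = None,
) -> list[list[SimIndividual]]:
    """Breed F1..F_k by random within-line mating; returns one list per generation.

    F1 individuals are all offspring of the two founders; each later
    generation is produced by drawing a random (female, male) parent pair from
    the previous generation per offspring.  ``final_size`` optionally enlarges
    the last generation (e.g. to phenotype enough females).
    """
    if generations < 2:
        raise ConfigurationError("generations must be >= 2 (F2 is the minimum)")
    if pop_size < 2:
        raise ConfigurationError("pop_size must be >= 2")
    mother, father = founders
    if mother.sex != "F" or father.sex != "M":
        raise ConfigurationError("founders must be (female, male)")

    out: list[list[SimIndividual]] = []
    current = [mother, father]
    for gen in range(1, generations + 1):
        n = final_size if (gen == generations and final_size) else pop_size
        sexes = _sexes(n, rng)
        females = [i for i in current if i.sex == "F"]
        males = [i for i in current if i.sex == "M"]
        children = [
            _offspring(
                females[rng.integers(len(females))],
                males[rng.integers(len(males))],
                layout,
                gen,
                sexes[i],
                rng,
            )
            for i in range(n)
        ]
        out.append(children)
        current = children
    return out


def genotype_dosage(
    individuals: list[SimIndividual],
    founder_alleles: np.ndarray,
    sites_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    n_sites: int,
) -> np.ndarray:
    """Reference-allele dosage (n_sites, n_individuals) from ancestry + founder alleles."""
    out = np.zeros((n_sites, len(individuals)), dtype=np.int8)
    for j, ind in enumerate(individuals):
        for chrom, (idx, positions) in sites_by_chrom.items():
            for hap in ind.haplotypes[chrom]:
                fid = hap.founder_at(positions)
                out[idx, j] += founder_alleles[fid, idx]
    return out


def map_expansion_ratio(
    layout: GenomeLayout,
    seed: int,
    n_gametes: int = 10_000,
    pop_size: int = 1_000,
    high_generation: int = 7,
) -> float:
    """Simulated F_k : F2 ratio of mean lineage crossover counts.

    Breeds one intercross line to F_{k-1}, then draws ``n_gametes``
    transmitted gametes from random F1 individuals (these would produce F2
    offspring) and from random F_{k-1} individuals (producing F_k offspring),
    comparing the mean crossover events accumulated along each gamete's
    meiotic lineage.  The expectation is k - 1 : 1, i.e. 6 at F7.
    """
    rng = np.random.default_rng(seed)
    founders = founder_pair(layout)
    gens = breed_intercross(layout, founders, high_generation - 1, pop_size, rng)
    f1, f_last = gens[0], gens[-1]

    def mean_lineage(parents: list[SimIndividual]) -> float:
        total = 0.0
        for _ in range(n_gametes):
            g = make_gamete(parents[rng.integers(len(parents))], layout, rng)
            total += sum(h.lineage_crossovers for h in g.values())
        return total / n_gametes

    return mean_lineage(f_last) / mean_lineage(f1)


def temp_ancestry_fraction(ind: SimIndividual) -> float:
    """Genome-wide fraction of bp with TEMP-founder ancestry (both haplotypes)."""
    total = 0
    temp = 0
    for haps in ind.haplotypes.values():
        for hap in haps:
            ends = np.append(hap.starts[1:] - 1, hap.length)
            lengths = ends - hap.starts + 1
            total += int(lengths.sum())
            mask = np.isin(hap.founders, TEMP_FOUNDER_HAPS)
            temp += int(lengths[mask].sum())
    return temp / total
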