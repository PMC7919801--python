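"""Genome layout: physical and genetic lengths of the pseudochromosomes."""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a layout or simulation configuration is invalid."""


@dataclass(frozen=True)
class Chromosome:
    """One pseudochromosome with a linear genetic <-> physical map."""

    id: str
    physical_length: int  # bp
    genetic_length: float  # cM

    def __post_init__(self) -> None:
        if self.physical_length <= 0:
            raise ConfigurationError(
                f"chromosome {self.id!r}: physical_length must be > 0"
            )
        if self.genetic_length <= 0:
            raise ConfigurationError(
                f"chromosome {self.id!r}: genetic_length must be > 0"
            )

    def cm_to_bp(self, cm: float) -> int:
        """Map a genetic position (cM) to a physical position (bp), linearly."""
        frac = cm / self.genetic_length
        pos = int(round(frac * self.physical_length))
        return min(max(pos, 1), self.physical_length)


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered set of chromosomes with unique ids.

    The default layout mirrors the three A. albopictus pseudochromosomes:
    587, 491 and 372 Mb, each with a genetic length of about 50 cM.
    """

    chromosomes: tuple[Chromosome, ...] = field(
        default_factory=lambda: (
            Chromosome("1", 587_000_000, 50.0),
            Chromosome("2", 491_000_000, 50.0),
            Chromosome("3", 372_000_000, 50.0),
        )
    )

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ConfigurationError(f"duplicate chromosome ids in {ids}")
        if not ids:
            raise ConfigurationError("layout needs at least one chromosome")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __getitem__(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.chromosomes]

    @classmethod
    def from_dict(cls, entries: list[dict]) -> "GenomeLayout":
        """Build from a list of {id, physical_length, genetic_length} dicts."""
        return cls(
            tuple(
                Chromosome(
                    str(d["id"]),
                    int(d["physical_length"]),
                    float(d["genetic_length"]),
                )
                for d in entries
            )
        )
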