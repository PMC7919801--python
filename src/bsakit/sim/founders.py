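"""Founder populations, SNP sites and QTL effects for the intercross."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bsakit.layout import ConfigurationError, GenomeLayout

TEMP_FOUNDER_HAPS = (0, 1)  # the F0 TEMP female's two haplotypes
TROP_FOUNDER_HAPS = (2, 3)  # the F0 TROP male's two haplotypes


@dataclass(frozen=True)
class QtlLocus:
    """A diapause liability locus: effect per TEMP-ancestry allele."""

    chrom: str
    pos: int
    effect: float


@dataclass
class FounderModel:
    """Per-site reference-allele frequencies in the two source populations.

    ``sites`` holds (chrom, pos, ref, alt); ``temp_freq`` / ``trop_freq`` are
    the population reference-allele frequencies the founder haplotypes and
    panel individuals are drawn from.  A configurable fraction of sites is
    strongly differentiated between the populations (frequency gap
    ``diff_gap`` centred on 0.5, random orientation), emulating the roughly
    one-in-ten SNPs that differ between temperate and tropical samples.
    """

    sites: pd.DataFrame
    temp_freq: np.ndarray
    trop_freq: np.ndarray
    qtls: list[QtlLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        for arr, name in ((self.temp_freq, "temp_freq"), (self.trop_freq, "trop_freq")):
            if len(arr) != len(self.sites):
                raise ConfigurationError(f"{name} length != number of sites")
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError(f"{name} outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate_qtls(self, layout: GenomeLayout) -> None:
        for q in self.qtls:
            try:
                chrom = layout[q.chrom]
            except KeyError:
                raise ConfigurationError(f"QTL on unknown chromosome {q.chrom!r}")
            if not (1 <= q.pos <= chrom.physical_length):
                raise ConfigurationError(
                    f"QTL position {q.pos} outside chromosome {q.chrom}"
                )

    @classmethod
    def random(
        cls,
        layout: GenomeLayout,
        n_sites: int,
        rng: np.random.Generator,
        frac_differentiated: float = 0.10,
        diff_gap: float = 0.9,
        qtls: list[QtlLocus] | None = None,
    ) -> "FounderModel":
        """Draw sites uniformly over the genome with the given divergence.

        Non-differentiated sites share one frequency (Uniform(0.05, 0.95)) in
        both populations; differentiated sites get 0.5 +/- diff_gap/2 with a
        coin-flip orientation.
        """
        lengths = np.array([c.physical_length for c in layout], dtype=float)
        probs = lengths / lengths.sum()
        chrom_idx = rng.choice(len(lengths), size=n_sites, p=probs)
        pos = (rng.random(n_sites) * lengths[chrom_idx]).astype(np.int64) + 1
        ids = np.array(layout.ids)
        order = np.lexsort((pos, chrom_idx))
        chrom_idx, pos = chrom_idx[order], pos[order]
        # keep positions unique per chromosome so sites are distinct
        for c in range(len(lengths)):
            m = chrom_idx == c
            p = pos[m]
            dup = np.concatenate(([False], np.diff(p) == 0))
            while dup.any():
                p[dup] += 1
                p.sort()
                dup = np.concatenate(([False], np.diff(p) == 0))
            pos[m] = np.minimum(p, int(lengths[c]))

        base = rng.uniform(0.05, 0.95, size=n_sites)
        temp = base.copy()
        trop = base.copy()
        n_diff = int(round(frac_differentiated * n_sites))
        diff_idx = rng.choice(n_sites, size=n_diff, replace=False)
        orient = rng.random(n_diff) < 0.5
        hi, lo = 0.5 + diff_gap / 2.0, 0.5 - diff_gap / 2.0
        temp[diff_idx] = np.where(orient, hi, lo)
        trop[diff_idx] = np.where(orient, lo, hi)

        ref = rng.choice(list("ACGT"), size=n_sites)
        alt_offset = rng.integers(1, 4, size=n_sites)
        bases = np.array(list("ACGT"))
        base_idx = np.searchsorted(bases, ref)
        alt = bases[(base_idx + alt_offset) % 4]

        sites = pd.DataFrame(
            {"chrom": ids[chrom_idx], "pos": pos, "ref": ref, "alt": alt}
        )
        model = cls(sites=sites, temp_freq=temp, trop_freq=trop, qtls=list(qtls or []))
        model.validate_qtls(layout)
        return model

    def draw_founder_alleles(self, rng: np.random.Generator) -> np.ndarray:
        """(4, n_sites) 0/1 matrix: 1 = reference allele on that founder haplotype."""
        alleles = np.empty((4, self.n_sites), dtype=np.int8)
        for h in TEMP_FOUNDER_HAPS:
            alleles[h] = rng.random(self.n_sites) < self.temp_freq
        for h in TROP_FOUNDER_HAPS:
            alleles[h] = rng.random(self.n_sites) < self.trop_freq
        return alleles

    def draw_panel_genotypes(
        self, population: str, n_individuals: int, rng: np.random.Generator
    ) -> np.ndarray:
        """(n_sites, n_individuals) ref-allele dosages drawn from the population."""
        freq = {"temp": self.temp_freq, "trop": self.trop_freq}[population]
        return rng.binomial(
            2, freq[:, None], size=(self.n_sites, n_individuals)
        ).astype(np.int8)

    def sites_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (site row indices, positions), positions ascending."""
        out = {}
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            out[str(chrom)] = (
                grp.index.to_numpy(),
                grp["pos"].to_numpy(dtype=np.int64),
            )
        return out
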