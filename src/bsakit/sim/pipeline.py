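"""End-to-end study simulation: founders -> intercross -> bulks -> SnpTable.

:class:`StudyDesign` captures the study conditions: a single F0 TEMP female x
TROP male pair founding two intercross lines bred to F4 by random within-line
mating (census 100); 60 phenotyped females with 20-64 eggs in line 1 and 78
with 22-69 eggs in line 2; low-diapause bulks at DI <= 10% (line 1) / 5%
(line 2) and high-diapause bulks at DI >= 50%, truncated to sizes 11/11 and
12/8; panels of 11 TEMP and 9 TROP individuals including the parents; and
pooled-RNAseq binomial read counts over negative-binomial depths.

Randomness is hierarchical: one master seed spawns independent child streams
per stage, so e.g. the phenotyping draw does not perturb the breeding draw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from bsakit.layout import GenomeLayout
from bsakit.snptable import SnpTable
from bsakit.sim.breeding import (
    SimIndividual,
    breed_intercross,
    founder_pair,
    genotype_dosage,
)
from bsakit.sim.counts import simulate_read_counts
from bsakit.sim.founders import FounderModel, QtlLocus
from bsakit.sim.phenotype import BulkSpec, Bulks, assign_phenotypes, form_bulks

logger = logging.getLogger(__name__)

_STAGES = (
    "founder_model",
    "founder_alleles",
    "breed_line1",
    "breed_line2",
    "pheno_line1",
    "pheno_line2",
    "counts",
    "panels",
)


@dataclass
class StudyDesign:
    layout: GenomeLayout = field(default_factory=GenomeLayout)
    n_sites: int = 50_000
    frac_differentiated: float = 0.10
    diff_gap: float = 0.9
    qtls: list[QtlLocus] = field(default_factory=list)
    intercept: float = 0.0
    liability_sd: float = 2.0
    pop_size: int = 100
    bulk_generation: int = 4
    n_phenotyped: dict[int, int] = field(default_factory=lambda: {1: 60, 2: 78})
    egg_ranges: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (20, 64), 2: (22, 69)}
    )
    bulk_specs: dict[int, BulkSpec] = field(
        default_factory=lambda: {1: BulkSpec.line1(), 2: BulkSpec.line2()}
    )
    n_temp_panel: int = 11
    n_trop_panel: int = 9
    panel_missing_rate: float = 0.10
    mean_depth: float = 60.0
    depth_dispersion: float = 5.0

    @classmethod
    def from_dict(cls, cfg: dict) -> "StudyDesign":
        kwargs: dict = {}
        if "layout" in cfg:
            kwargs["layout"] = GenomeLayout.from_dict(cfg["layout"])
        if "qtls" in cfg:
            kwargs["qtls"] = [
                QtlLocus(str(q["chrom"]), int(q["pos"]), float(q["effect"]))
                for q in cfg["qtls"]
            ]
        for key in (
            "n_sites",
            "frac_differentiated",
            "diff_gap",
            "intercept",
            "liability_sd",
            "pop_size",
            "bulk_generation",
            "n_temp_panel",
            "n_trop_panel",
            "panel_missing_rate",
            "mean_depth",
            "depth_dispersion",
        ):
            if key in cfg:
                kwargs[key] = cfg[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class StudyResult:
    table: SnpTable
    truth: dict
    founder_model: FounderModel
    bulks: dict[int, Bulks]
    phenotyped: dict[int, list]


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def run_study(design: StudyDesign, seed: int) -> StudyResult:
    """Simulate the full study once and assemble the pipeline input table."""
    rngs = _stage_rngs(seed)
    logger.info("run_study: master seed %d", seed)
    model = FounderModel.random(
        design.layout,
        design.n_sites,
        rngs["founder_model"],
        frac_differentiated=design.frac_differentiated,
        diff_gap=design.diff_gap,
        qtls=design.qtls,
    )
    alleles = model.draw_founder_alleles(rngs["founder_alleles"])
    sites_by_chrom = model.sites_by_chrom()
    f0_female, f0_male = founder_pair(design.layout)

    bulks: dict[int, Bulks] = {}
    phenotyped: dict[int, list] = {}
    bulk_counts = {}
    count_rng = rngs["counts"]
    for line in (1, 2):
        n_pheno = design.n_phenotyped[line]
        # ~half the final generation is female; oversample so the design's
        # phenotyped-female counts are realized essentially always
        final_size = max(design.pop_size, math.ceil(3.0 * n_pheno))
        gens = breed_intercross(
            design.layout,
            (f0_female, f0_male),
            design.bulk_generation,
            design.pop_size,
            rngs[f"breed_line{line}"],
            final_size=final_size,
        )
        females = [i for i in gens[-1] if i.sex == "F"][:n_pheno]
        if len(females) < n_pheno:
            logger.warning(
                "line %d: only %d females available of %d requested",
                line,
                len(females),
                n_pheno,
            )
        ph = assign_phenotypes(
            females,
            design.qtls,
            rngs[f"pheno_line{line}"],
            intercept=design.intercept,
            liability_sd=design.liability_sd,
            egg_range=design.egg_ranges[line],
        )
        phenotyped[line] = ph
        b = form_bulks(ph, design.bulk_specs[line])
        bulks[line] = b
        for cls_, members in (("low", b.low), ("high", b.high)):
            if not members:
                zeros = np.zeros(design.n_sites, dtype=np.int64)
                bulk_counts[(line, cls_)] = (zeros, zeros.copy())
                continue
            dos = genotype_dosage(
                [f.individual for f in members],
                alleles,
                sites_by_chrom,
                design.n_sites,
            )
            bulk_counts[(line, cls_)] = simulate_read_counts(
                dos, design.mean_depth, design.depth_dispersion, count_rng
            )

    panel_rng = rngs["panels"]
    pf = (alleles[0] + alleles[1]).astype(np.int8)
    pm = (alleles[2] + alleles[3]).astype(np.int8)
    temp_gt = np.column_stack(
        [pf, model.draw_panel_genotypes("temp", design.n_temp_panel - 1, panel_rng)]
    ).astype(np.int8)
    trop_gt = np.column_stack(
        [pm, model.draw_panel_genotypes("trop", design.n_trop_panel - 1, panel_rng)]
    ).astype(np.int8)
    if design.panel_missing_rate > 0:
        temp_gt[panel_rng.random(temp_gt.shape) < design.panel_missing_rate] = -1
        trop_gt[panel_rng.random(trop_gt.shape) < design.panel_missing_rate] = -1
        # the F0 parents were deeply sequenced; keep their calls complete
        temp_gt[:, 0] = pf
        trop_gt[:, 0] = pm

    temp_names = ["F0_female"] + [f"temp_{i:02d}" for i in range(2, design.n_temp_panel + 1)]
    trop_names = ["F0_male"] + [f"trop_{i:02d}" for i in range(2, design.n_trop_panel + 1)]
    table = SnpTable(
        sites=model.sites.copy(),
        temp_gt=temp_gt,
        trop_gt=trop_gt,
        parent_female=pf,
        parent_male=pm,
        bulk_counts=bulk_counts,
        temp_names=temp_names,
        trop_names=trop_names,
    )
    truth = {
        "seed": int(seed),
        "qtls": [
            {"chrom": q.chrom, "pos": int(q.pos), "effect": float(q.effect)}
            for q in design.qtls
        ],
        "n_sites": int(design.n_sites),
        "bulk_sizes": {
            f"{line}:{cls_}": len(getattr(bulks[line], cls_))
            for line in (1, 2)
            for cls_ in ("low", "high")
        },
        "flags": {line: bulks[line].flags for line in (1, 2)},
        "di": {
            line: [round(f.di_observed, 4) for f in phenotyped[line]]
            for line in (1, 2)
        },
    }
    return StudyResult(
        table=table,
        truth=truth,
        founder_model=model,
        bulks=bulks,
        phenotyped=phenotyped,
    )
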