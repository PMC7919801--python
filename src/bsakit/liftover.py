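"""Assembly-reassembly bookkeeping: contig liftover, chimeric-scaffold cuts,
reciprocal-best-hit ortholog filtering and the intercross map-expansion
correction.

Interchange coordinates are 1-based inclusive everywhere (GFF3/AGP
convention).  A feature lifts through a contig placement only when it lies
entirely within the placed source interval; features crossing a contig
boundary or sitting on unplaced sequence are rejected with machine-readable
reasons, mirroring how annotations survive a whole-contig reassembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from bsakit.annotate import FeatureRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContigPlacement:
    """A source-assembly contig interval placed on a target scaffold."""

    contig_id: str
    source_scaffold: str
    source_start: int  # 1-based inclusive
    source_end: int
    target_scaffold: str
    target_start: int
    target_end: int
    orientation: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.source_end - self.source_start != self.target_end - self.target_start:
            raise ValueError(
                f"placement {self.contig_id}: source and target lengths differ"
            )
        if self.orientation not in "+-":
            raise ValueError(f"placement {self.contig_id}: bad orientation")


@dataclass(frozen=True)
class Rejection:
    feature_id: str
    reason: str  # 'split', 'unplaced', 'cut'


def read_placements_agp(path: str | Path) -> list[ContigPlacement]:
    """AGP 2.1 component (W) lines -> placements; gaps (N/U) are skipped.

    AGP columns: object, object_beg, object_end, part_number, component_type,
    component_id, component_beg, component_end, orientation.  The AGP object
    is the *target* scaffold; the component is the placed contig.  A '?'
    (or 0/na) orientation is treated as '+' with a warning.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: malformed AGP at line {lineno}")
            if parts[4] in ("N", "U"):
                continue
            orientation = parts[8]
            if orientation not in "+-":
                logger.warning(
                    "%s line %d: orientation %r treated as '+'",
                    path,
                    lineno,
                    orientation,
                )
                orientation = "+"
            out.append(
                ContigPlacement(
                    contig_id=parts[5],
                    source_scaffold=parts[5],
                    source_start=int(parts[6]),
                    source_end=int(parts[7]),
                    target_scaffold=parts[0],
                    target_start=int(parts[1]),
                    target_end=int(parts[2]),
                    orientation=orientation,
                )
            )
    return out


def read_placements_tsv(path: str | Path) -> list[ContigPlacement]:
    """TSV fallback with explicit source coordinates (one header row)."""
    df = pd.read_csv(path, sep="\t", dtype={"source_scaffold": str, "target_scaffold": str})
    return [
        ContigPlacement(
            contig_id=str(r.contig_id),
            source_scaffold=str(r.source_scaffold),
            source_start=int(r.source_start),
            source_end=int(r.source_end),
            target_scaffold=str(r.target_scaffold),
            target_start=int(r.target_start),
            target_end=int(r.target_end),
            orientation=str(r.orientation),
        )
        for r in df.itertuples(index=False)
    ]


def lift_feature(
    feature: FeatureRecord, placements: list[ContigPlacement]
) -> FeatureRecord | Rejection:
    """Lift a feature through the placement containing it entirely.

    '+' placements shift coordinates; '-' placements reflect them within the
    target interval and flip the strand.  Length is preserved exactly.
    """
    candidates = [
        p
        for p in placements
        if p.source_scaffold == feature.chrom
        and not (feature.end < p.source_start or feature.start > p.source_end)
    ]
    containing = [
        p
        for p in candidates
        if p.source_start <= feature.start and feature.end <= p.source_end
    ]
    if not containing:
        reason = "split" if candidates else "unplaced"
        return Rejection(feature_id=feature.feature_id, reason=reason)
    p = containing[0]
    if p.orientation == "+":
        new_start = p.target_start + (feature.start - p.source_start)
        new_end = p.target_start + (feature.end - p.source_start)
        strand = feature.strand
    else:
        new_start = p.target_end - (feature.end - p.source_start)
        new_end = p.target_end - (feature.start - p.source_start)
        strand = {"+": "-", "-": "+"}.get(feature.strand, feature.strand)
    return FeatureRecord(
        feature_id=feature.feature_id,
        feature_class=feature.feature_class,
        chrom=p.target_scaffold,
        start=new_start,
        end=new_end,
        strand=strand,
    )


def invert_placements(placements: list[ContigPlacement]) -> list[ContigPlacement]:
    """Swap source and target, preserving orientation; the liftover inverse."""
    return [
        ContigPlacement(
            contig_id=p.contig_id,
            source_scaffold=p.target_scaffold,
            source_start=p.target_start,
            source_end=p.target_end,
            target_scaffold=p.source_scaffold,
            target_start=p.source_start,
            target_end=p.source_end,
            orientation=p.orientation,
        )
        for p in placements
    ]


@dataclass(frozen=True)
class ScaffoldFragment:
    fragment_id: str
    length: int


def cut_scaffold(
    scaffold_id: str,
    length: int,
    cut: int,
    features: list[FeatureRecord] | None = None,
) -> tuple[
    tuple[ScaffoldFragment, ScaffoldFragment],
    list[FeatureRecord],
    list[Rejection],
]:
    """Cut a (chimeric) scaffold after ``cut`` bases.

    Returns two fragments of lengths ``cut`` and ``length - cut``
    (fragment ids ``<id>.1`` / ``<id>.2``), plus any features re-indexed onto
    the fragments; features spanning the cut are rejected with reason 'cut'.
    """
    if not (0 < cut < length):
        raise ValueError(f"cut position {cut} outside (0, {length})")
    frag1 = ScaffoldFragment(f"{scaffold_id}.1", cut)
    frag2 = ScaffoldFragment(f"{scaffold_id}.2", length - cut)
    lifted: list[FeatureRecord] = []
    rejected: list[Rejection] = []
    for f in features or []:
        if f.chrom != scaffold_id:
            lifted.append(f)
        elif f.end <= cut:
            lifted.append(replace(f, chrom=frag1.fragment_id))
        elif f.start > cut:
            lifted.append(
                replace(
                    f,
                    chrom=frag2.fragment_id,
                    start=f.start - cut,
                    end=f.end - cut,
                )
            )
        else:
            rejected.append(Rejection(feature_id=f.feature_id, reason="cut"))
    return (frag1, frag2), lifted, rejected


# ------------------------------------------------------------------ RBH


def _best_hits(hits: pd.DataFrame, e_max: float, id_min: float, cov_min: float) -> dict:
    """Best subject per query after threshold filtering.

    Best = highest bit-score; ties broken by lexicographically smallest
    subject id, so results are deterministic.
    """
    ok = hits.loc[
        (hits["evalue"] <= e_max)
        & (hits["pident"] >= id_min)
        & (hits["qcov"] >= cov_min)
    ]
    best: dict[str, tuple[float, str]] = {}
    for r in ok.itertuples(index=False):
        key = (float(r.bitscore), str(r.subject))
        prev = best.get(r.query)
        if prev is None or key[0] > prev[0] or (key[0] == prev[0] and key[1] < prev[1]):
            best[r.query] = key
    return {q: s for q, (_, s) in best.items()}


def rbh_pairs(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    e_max: float = 1e-20,
    id_min: float = 85.0,
    cov_min: float = 50.0,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two protein sets.

    Each hit table needs columns query, subject, evalue, pident, qcov,
    bitscore.  Defaults match the ortholog screen: e-value <= 1e-20,
    percent identity >= 85, query coverage >= 50.
    """
    best_ab = _best_hits(hits_ab, e_max, id_min, cov_min)
    best_ba = _best_hits(hits_ba, e_max, id_min, cov_min)
    return sorted(
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    )


# -------------------------------------------------- map-expansion correction


def map_expansion_factor(generation: int) -> int:
    """Meioses per transmitted-gamete lineage from F1 in an F_k intercross.

    F_k offspring accumulate k - 1 rounds of meiosis, so naive genetic
    distances estimated as if they were F2 offspring are inflated k - 1 fold
    (6 at F7).
    """
    if generation < 2:
        raise ValueError("map expansion defined for intercross generations >= 2")
    return generation - 1


@dataclass(frozen=True)
class CorrectedLengths:
    raw_cm: tuple[float, ...]
    corrected_cm: tuple[float, ...]
    factor: float
    lower_bound: bool = True  # undetected double crossovers make this a floor


def correct_genetic_lengths(
    raw_lengths_cm: list[float], factor: float
) -> CorrectedLengths:
    """Divide apparent genetic lengths by the map-expansion factor.

    The result is flagged as a lower bound: multiple undetected crossovers
    between markers can only shrink the apparent map further.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if any(x <= 0 for x in raw_lengths_cm):
        raise ValueError("genetic lengths must be positive")
    corrected = tuple(x / factor for x in raw_lengths_cm)
    return CorrectedLengths(
        raw_cm=tuple(raw_lengths_cm),
        corrected_cm=corrected,
        factor=float(factor),
        lower_bound=True,
    )
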