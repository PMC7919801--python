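"""Annotation proximity: features within 50 kb of candidate SNPs, per tier.

Features are read from GFF3 (1-based inclusive coordinates) and grouped into
the summary classes used for the candidate-region tables: protein-coding
genes, lncRNAs, pseudogenes, and "other" (tRNA + miscellaneous RNA).  A
feature is "nearby" a SNP when the distance from the SNP position to the
nearest edge of the feature interval is at most the search distance
(boundary inclusive; 0 when the SNP lies inside the feature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_CLASSES: dict[str, str] = {
    # GFF3 feature type -> summary class
    "gene": "gene",
    "protein_coding_gene": "gene",
    "lnc_RNA": "lncRNA",
    "lncRNA": "lncRNA",
    "ncRNA_gene": "lncRNA",
    "pseudogene": "pseudogene",
    "tRNA": "other",
    "tRNA_gene": "other",
    "misc_RNA": "other",
}

TIER_ORDER = ("fp0.05", "fp1", "fp5")


@dataclass(frozen=True)
class FeatureRecord:
    feature_id: str
    feature_class: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}"
            )


def load_features(
    gff3_path: str | Path, classes: dict[str, str] | None = None
) -> list[FeatureRecord]:
    """Top-level features of the configured classes from a GFF3 file.

    A feature whose parent is itself selected (e.g. a tRNA inside a selected
    gene) is skipped so each locus is represented once.  Malformed lines are
    reported with their line number.
    """
    import gffutils

    classes = DEFAULT_CLASSES if classes is None else classes
    with open(gff3_path) as fh:
        has_records = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_records:
        return []
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise _annotate_parse_error(gff3_path, exc) from exc

    selected: dict[str, FeatureRecord] = {}
    for feat in db.all_features():
        if feat.featuretype not in classes:
            continue
        selected[feat.id] = FeatureRecord(
            feature_id=feat.id,
            feature_class=classes[feat.featuretype],
            chrom=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand or ".",
        )
    # drop children of selected parents
    out = []
    for fid, rec in selected.items():
        parents = {p.id for p in db.parents(fid)}
        if parents & selected.keys():
            continue
        out.append(rec)
    return out


def _annotate_parse_error(path, exc) -> ValueError:
    """Attach a line number to a GFF3 parse failure when one can be found."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                if len(line.rstrip("\n").split("\t")) != 9:
                    return ValueError(
                        f"{path}: malformed GFF3 at line {lineno}: {line.strip()!r}"
                    )
    except OSError:
        pass
    return ValueError(f"{path}: cannot parse GFF3 ({exc})")


def features_within_distance(
    snps: pd.DataFrame,
    features: list[FeatureRecord],
    distance: int = 50_000,
) -> dict[int, list[FeatureRecord]]:
    """Map each SNP (rows with chrom, pos) to the features within ``distance`` bp.

    SNPs on chromosomes absent from the annotation map to an empty list.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in features:
        # store 1-based inclusive [start, end] as half-open [start, end+1)
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end + 1, rec)
    out: dict[int, list[FeatureRecord]] = {}
    for idx, row in zip(snps.index, snps.itertuples(index=False)):
        tree = trees.get(str(row.chrom))
        if tree is None:
            out[idx] = []
            continue
        pos = int(row.pos)
        hits = tree.overlap(pos - distance, pos + distance + 1)
        out[idx] = sorted((h.data for h in hits), key=lambda r: (r.start, r.feature_id))
    return out


def snp_feature_distance(pos: int, rec: FeatureRecord) -> int:
    """Distance from a SNP to the nearest edge of a feature (0 if inside)."""
    if rec.start <= pos <= rec.end:
        return 0
    return rec.start - pos if pos < rec.start else pos - rec.end


@dataclass
class ProximityReport:
    """Per-tier counts of SNPs, scaffolds, and distinct nearby features by class."""

    summary: pd.DataFrame  # rows: count categories, columns: tiers
    per_snp: pd.DataFrame  # long table: one row per (SNP, nearby feature)


def summarize_tiers(
    candidates: pd.DataFrame,
    mapping: dict[int, list[FeatureRecord]],
    tiers: tuple[str, ...] = TIER_ORDER,
) -> ProximityReport:
    """Candidate-region summary per tier (each tier includes the stricter ones).

    ``candidates`` needs columns chrom, pos, tier; ``mapping`` is the output
    of :func:`features_within_distance` keyed by the same index.  Nearby
    features are deduplicated by feature id within each tier row.
    """
    rows = ["n_snps", "n_scaffolds", "gene", "lncRNA", "pseudogene", "other"]
    summary = pd.DataFrame(0, index=rows, columns=list(tiers))
    long_rows = []
    for t_i, tier in enumerate(tiers):
        allowed = set(tiers[: t_i + 1])
        sub = candidates.loc[candidates["tier"].isin(allowed)]
        summary.loc["n_snps", tier] = len(sub)
        summary.loc["n_scaffolds", tier] = sub["chrom"].nunique()
        seen: dict[str, set[str]] = {c: set() for c in rows[2:]}
        for idx in sub.index:
            for rec in mapping.get(idx, []):
                seen[rec.feature_class].add(rec.feature_id)
        for cls_, ids in seen.items():
            summary.loc[cls_, tier] = len(ids)
    for idx in candidates.index:
        tier = candidates.at[idx, "tier"]
        if tier not in tiers:
            continue
        for rec in mapping.get(idx, []):
            long_rows.append(
                {
                    "chrom": candidates.at[idx, "chrom"],
                    "pos": int(candidates.at[idx, "pos"]),
                    "tier": tier,
                    "feature_id": rec.feature_id,
                    "feature_class": rec.feature_class,
                    "feature_start": rec.start,
                    "feature_end": rec.end,
                    "strand": rec.strand,
                    "distance": snp_feature_distance(
                        int(candidates.at[idx, "pos"]), rec
                    ),
                }
            )
    per_snp = pd.DataFrame(
        long_rows,
        columns=[
            "chrom",
            "pos",
            "tier",
            "feature_id",
            "feature_class",
            "feature_start",
            "feature_end",
            "strand",
            "distance",
        ],
    )
    return ProximityReport(summary=summary, per_snp=per_snp)
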