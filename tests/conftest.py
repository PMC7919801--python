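"""Shared fixtures: small layouts, hand-built SNP tables, tiny annotations."""

import numpy as np
import pandas as pd
import pytest

from bsakit.layout import Chromosome, GenomeLayout
from bsakit.snptable import BULK_KEYS, SnpTable


@pytest.fixture
def small_layout() -> GenomeLayout:
    """One short chromosome, full-length genetic map (fast breeding)."""
    return GenomeLayout((Chromosome("1", 20_000_000, 50.0),))


@pytest.fixture
def single_big_chrom() -> GenomeLayout:
    """One chromosome at the study's chromosome-1 scale."""
    return GenomeLayout((Chromosome("1", 587_000_000, 50.0),))


def make_table(
    sites: pd.DataFrame,
    temp_gt: np.ndarray,
    trop_gt: np.ndarray,
    parent_female: np.ndarray,
    parent_male: np.ndarray,
    bulk_counts: dict | None = None,
) -> SnpTable:
    """SnpTable with any missing bulk filled with depth-20 ref-only counts."""
    n = len(sites)
    bulk_counts = dict(bulk_counts or {})
    for key in BULK_KEYS:
        bulk_counts.setdefault(
            key, (np.full(n, 20, dtype=np.int64), np.zeros(n, dtype=np.int64))
        )
    return SnpTable(
        sites=sites,
        temp_gt=np.asarray(temp_gt, dtype=np.int8),
        trop_gt=np.asarray(trop_gt, dtype=np.int8),
        parent_female=np.asarray(parent_female, dtype=np.int8),
        parent_male=np.asarray(parent_male, dtype=np.int8),
        bulk_counts=bulk_counts,
    )


def sites_frame(n: int, chrom: str = "1", start: int = 1000, step: int = 1000):
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": np.arange(start, start + n * step, step)[:n],
            "ref": ["A"] * n,
            "alt": ["T"] * n,
        }
    )


TINY_GFF = """##gff-version 3
chr1\ttest\tgene\t100\t200\t.\t+\t.\tID=gene1;Name=g1
chr1\ttest\tmRNA\t100\t200\t.\t+\t.\tID=rna1;Parent=gene1
chr1\ttest\texon\t100\t150\t.\t+\t.\tID=exon1;Parent=rna1
chr1\ttest\ttRNA\t120\t140\t.\t+\t.\tID=trna_in_gene;Parent=gene1
chr1\ttest\tlnc_RNA\t5000\t6000\t.\t-\t.\tID=lnc1
chr1\ttest\tpseudogene\t9000\t9500\t.\t+\t.\tID=pg1
chr2\ttest\ttRNA\t300\t400\t.\t-\t.\tID=trna1
"""


@pytest.fixture
def tiny_gff(tmp_path):
    path = tmp_path / "tiny.gff3"
    path.write_text(TINY_GFF)
    return path
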