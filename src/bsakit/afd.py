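"""Allele frequency differences (AFDs) and the completeness / concordance filters.

For every SNP three signed AFDs are computed with a fixed orientation:

* ``afd_pop``   = ref-allele frequency(TEMP panel) - frequency(TROP panel)
* ``afd_line1`` = frequency(high-diapause bulk 1) - frequency(low bulk 1)
* ``afd_line2`` = frequency(high-diapause bulk 2) - frequency(low bulk 2)

Panel frequencies are allele-dosage means over non-missing individuals; bulk
frequencies are raw reference read fractions (no genotype-likelihood
shrinkage).  A SNP is concordant ("same sign") when all three AFDs are
non-zero and share a sign — the core evidence filter of the bulk-segregant
screen.  The minor allele frequency (MAF), which bounds the achievable
|AFD| and therefore stratifies the percentile p-values, is computed from the
pooled TEMP+TROP panel allele counts by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bsakit.snptable import BULK_KEYS, SnpTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterStats:
    n_input: int
    n_kept: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


def panel_freq(genotypes: np.ndarray, axis: int = -1) -> np.ndarray:
    """Reference-allele frequency from dosages (missing = -1 excluded).

    freq = sum(dosage) / (2 * n_nonmissing); NaN where all calls are missing.
    """
    g = np.array(genotypes, dtype=float, copy=True)
    g[g < 0] = np.nan
    with np.errstate(invalid="ignore"):
        n = np.sum(~np.isnan(g), axis=axis)
        total = np.nansum(g, axis=axis)
        return np.where(n > 0, total / (2.0 * np.maximum(n, 1)), np.nan)


def bulk_freq(ref_reads: np.ndarray, alt_reads: np.ndarray) -> np.ndarray:
    """Raw reference read fraction; NaN at zero depth."""
    ref = np.asarray(ref_reads, dtype=float)
    alt = np.asarray(alt_reads, dtype=float)
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(depth > 0, ref / np.maximum(depth, 1), np.nan)


def filter_completeness(
    table: SnpTable, min_panel: int = 5, min_bulk_depth: int = 1
) -> tuple[SnpTable, FilterStats]:
    """Keep sites genotyped in all four bulks and in >= min_panel individuals per panel.

    "Genotyped in a bulk" means the pooled read depth is at least
    ``min_bulk_depth`` (default 1 read).  Idempotent by construction.
    """
    keep = np.ones(table.n_sites, dtype=bool)
    for key in BULK_KEYS:
        ref, alt = table.bulk_counts[key]
        keep &= (ref + alt) >= min_bulk_depth
    keep &= np.sum(table.temp_gt >= 0, axis=1) >= min_panel
    keep &= np.sum(table.trop_gt >= 0, axis=1) >= min_panel
    stats = FilterStats(n_input=table.n_sites, n_kept=int(keep.sum()))
    if stats.n_kept == 0:
        logger.warning("completeness filter removed every site")
    logger.info(
        "completeness filter: kept %d / %d sites", stats.n_kept, stats.n_input
    )
    return table.subset(keep), stats


def _parental_config(pf: np.ndarray, pm: np.ndarray) -> pd.Series:
    """Unordered parental genotype pair as a string key; None when undefined.

    The key is defined only when both F0 genotypes are non-missing.  Pairs of
    identical homozygotes (0,0 or 2,2) are monomorphic in the cross; they keep
    a key but are flagged by :func:`is_monomorphic_config`.
    """
    lo = np.minimum(pf, pm)
    hi = np.maximum(pf, pm)
    keys = np.array([f"{a}/{b}" for a, b in zip(lo, hi)], dtype=object)
    keys[(pf < 0) | (pm < 0)] = None
    return pd.Series(keys)


def is_monomorphic_config(config: pd.Series) -> np.ndarray:
    """True for sites where both parents are identical homozygotes."""
    return config.isin(["0/0", "2/2"]).to_numpy()


def compute_afd(table: SnpTable, maf_panel: str = "pooled") -> pd.DataFrame:
    """One row per site: the three signed AFDs, MAF, parental config, concordance.

    ``maf_panel`` selects the allele-count pool for the MAF: "pooled"
    (TEMP+TROP, the default), "temp" or "trop".
    """
    if maf_panel not in ("pooled", "temp", "trop"):
        raise ValueError(f"unknown maf_panel {maf_panel!r}")
    f_temp = panel_freq(table.temp_gt)
    f_trop = panel_freq(table.trop_gt)

    freqs = {}
    for key in BULK_KEYS:
        freqs[key] = bulk_freq(*table.bulk_counts[key])

    df = table.sites[["chrom", "pos", "ref", "alt"]].copy()
    df["freq_temp"] = f_temp
    df["freq_trop"] = f_trop
    df["afd_pop"] = f_temp - f_trop
    df["afd_line1"] = freqs[(1, "high")] - freqs[(1, "low")]
    df["afd_line2"] = freqs[(2, "high")] - freqs[(2, "low")]

    panels = {
        "pooled": (table.temp_gt, table.trop_gt),
        "temp": (table.temp_gt,),
        "trop": (table.trop_gt,),
    }[maf_panel]
    gt = np.hstack(panels).astype(float)
    gt[gt < 0] = np.nan
    n_alleles = 2.0 * np.sum(~np.isnan(gt), axis=1)
    ref_count = np.nansum(gt, axis=1)
    with np.errstate(invalid="ignore"):
        ref_freq = np.where(n_alleles > 0, ref_count / np.maximum(n_alleles, 1), np.nan)
    df["maf"] = np.minimum(ref_freq, 1.0 - ref_freq)

    df["parental_config"] = _parental_config(table.parent_female, table.parent_male)
    signs = np.sign(df[["afd_pop", "afd_line1", "afd_line2"]].to_numpy())
    df["same_sign"] = (np.abs(signs).min(axis=1) > 0) & (
        np.abs(signs.sum(axis=1)) == 3
    )
    return df


def same_sign_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records where all three AFDs are non-zero and share a sign."""
    return records.loc[records["same_sign"].fillna(False).astype(bool)]


def segregating_filter(records: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Keep records with |afd_pop| strictly above ``threshold``.

    A large TEMP-TROP difference indicates the SNP segregates between the
    source populations in nature rather than only within the cross.
    """
    return records.loc[records["afd_pop"].abs() > threshold]
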