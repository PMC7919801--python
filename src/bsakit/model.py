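"""Model/Results front end for the bulk-segregant diapause screen.

``BulkSegregantModel`` wraps the full statistical pipeline — completeness
filtering, the three signed AFDs, same-sign concordance, stratified
percentile p-values, combined scores and expected-false-positive tiers — in
the fit/results idiom: build the model from a :class:`~bsakit.SnpTable`
(or a VCF/TSV path), call :meth:`~BulkSegregantModel.fit`, inspect the
returned :class:`BulkSegregantResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bsakit.afd import (
    FilterStats,
    compute_afd,
    filter_completeness,
    same_sign_filter,
)
from bsakit.significance import (
    SignificanceConfig,
    SignificanceResult,
    score_snps,
)
from bsakit.snptable import SnpTable


class BulkSegregantModel:
    """Bulk-segregant AFD model for a temperate x tropical intercross.

    Parameters
    ----------
    table : SnpTable
        Biallelic SNPs with panel genotypes and the four bulk read counts.
    min_panel : minimum non-missing genotypes per panel (completeness filter).
    min_bulk_depth : minimum pooled read depth per bulk ("genotyped in a bulk").
    maf_panel : allele pool for the MAF ('pooled', 'temp' or 'trop').
    maf_bin_width, min_bin : MAF stratification of the population comparison.
    afd_threshold : |AFD(TEMP,TROP)| a candidate must strictly exceed.
    fp_tiers : expected-false-positive counts defining the candidate tiers.
    """

    def __init__(
        self,
        table: SnpTable,
        *,
        min_panel: int = 5,
        min_bulk_depth: int = 1,
        maf_panel: str = "pooled",
        maf_bin_width: float = 0.05,
        min_bin: int = 200,
        afd_threshold: float = 0.5,
        fp_tiers: tuple[float, ...] = (0.05, 1.0, 5.0),
    ) -> None:
        self.table = table
        self.min_panel = min_panel
        self.min_bulk_depth = min_bulk_depth
        self.maf_panel = maf_panel
        self.sig_config = SignificanceConfig(
            maf_bin_width=maf_bin_width,
            min_bin=min_bin,
            fp_tiers=tuple(fp_tiers),
            afd_threshold=afd_threshold,
        )

    @classmethod
    def from_vcf(cls, path: str | Path, roles: dict | None = None, **kwargs):
        return cls(SnpTable.from_vcf(path, roles=roles), **kwargs)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs):
        return cls(SnpTable.from_tsv(path), **kwargs)

    def fit(
        self,
        method: str = "analytic",
        seed: int | None = None,
        empirical_replicates: int = 200,
    ) -> "BulkSegregantResults":
        """Run the screen; ``method`` picks the threshold calibration."""
        self.sig_config.method = method
        self.sig_config.empirical_replicates = empirical_replicates
        rng = np.random.default_rng(seed) if seed is not None else None

        filtered, stats = filter_completeness(
            self.table, self.min_panel, self.min_bulk_depth
        )
        afd_all = compute_afd(filtered, maf_panel=self.maf_panel)
        same_sign = same_sign_filter(afd_all)
        sig = score_snps(same_sign, self.sig_config, rng=rng)
        return BulkSegregantResults(
            model=self,
            filter_stats=stats,
            afd=afd_all,
            sig=sig,
        )


@dataclass
class BulkSegregantResults:
    """Fitted screen: per-SNP AFDs and p-values, thresholds and tier calls."""

    model: BulkSegregantModel
    filter_stats: FilterStats
    afd: pd.DataFrame  # all filtered sites with the three AFDs
    sig: SignificanceResult  # same-sign sites with p-values and tiers

    @property
    def table(self) -> pd.DataFrame:
        """Scored same-sign SNPs: AFDs, MAF, strata, p-values, tier."""
        return self.sig.table

    @property
    def thresholds(self) -> dict[float, float]:
        return self.sig.thresholds

    @property
    def n_filtered(self) -> int:
        return self.filter_stats.n_kept

    @property
    def n_same_sign(self) -> int:
        return len(self.sig.table)

    def candidates(self, tier: str = "fp5") -> pd.DataFrame:
        """Candidate SNPs at a tier, including the stricter nested tiers."""
        order = ["fp0.05", "fp1", "fp5"]
        if tier not in order:
            raise ValueError(f"unknown tier {tier!r}")
        allowed = order[: order.index(tier) + 1]
        t = self.sig.table
        return t.loc[t["tier"].isin(allowed)]

    def tier_counts(self) -> dict[str, int]:
        return {t: len(self.candidates(t)) for t in ("fp0.05", "fp1", "fp5")}

    def summary(self) -> str:
        """Plain-text summary in the spirit of a model results table."""
        cfg = self.model.sig_config
        counts = self.tier_counts()
        lines = [
            "Bulk-segregant diapause screen",
            "=" * 46,
            f"Sites passing completeness filter {self.n_filtered:>12,}",
            f"  (input sites {self.filter_stats.n_input:,}; "
            f"dropped {self.filter_stats.n_dropped:,})",
            f"Same-sign concordant SNPs         {self.n_same_sign:>12,}",
            f"  scored (parental config known)  {self.sig.n_scored:>12,}",
            f"MAF strata ({cfg.maf_bin_width:g}-wide, >= {cfg.min_bin})"
            f"{len(self.sig.maf_bin_edges):>10} bins",
            "-" * 46,
            "tier      exp. FP   threshold     candidates",
        ]
        for m in sorted(self.thresholds):
            name = {0.05: "fp0.05", 1.0: "fp1", 5.0: "fp5"}.get(m, f"fp{m:g}")
            lines.append(
                f"{name:<10}{m:>7g}   {self.thresholds[m]:.3e}  "
                f"{counts.get(name, 0):>10,}"
            )
        lines.append("-" * 46)
        lines.append(
            f"candidate rule: |AFD_pop| > {cfg.afd_threshold:g} and "
            "combined p < tier threshold"
        )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.sig.table.to_csv(path, sep="\t", index=False)

    def plot_manhattan(self, ax=None, layout=None):
        """|mean AFD| along the genome, candidates highlighted by tier."""
        import matplotlib.pyplot as plt

        t = self.sig.table
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        chroms = list(dict.fromkeys(t["chrom"]))
        offsets = {}
        off = 0
        for c in chroms:
            offsets[c] = off
            sub = t.loc[t["chrom"] == c, "pos"]
            span = (
                layout[c].physical_length
                if layout is not None
                else (int(sub.max()) if len(sub) else 0)
            )
            off += span
        x = t["pos"].to_numpy() + np.array([offsets[c] for c in t["chrom"]])
        y = t[["afd_pop", "afd_line1", "afd_line2"]].abs().mean(axis=1).to_numpy()
        ax.scatter(x, y, s=2, c="0.7", label="same-sign SNPs")
        styles = {"fp5": ("tab:red", 6), "fp1": ("tab:orange", 12), "fp0.05": ("tab:green", 24)}
        for tier, (color, size) in styles.items():
            m = (t["tier"] == tier).to_numpy()
            if m.any():
                ax.scatter(x[m], y[m], s=size, c=color, label=tier)
        for c in chroms[1:]:
            ax.axvline(offsets[c], ls="--", lw=0.5, c="k")
        ax.set_xlabel("genome position (bp, chromosomes concatenated)")
        ax.set_ylabel("mean |AFD|")
        ax.legend(fontsize=7, loc="upper right")
        return ax
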