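"""Stratified empirical percentile p-values and expected-false-positive calibration.

Each concordant SNP receives three p-values, one per comparison:

* the TEMP-TROP comparison, stratified by minor-allele-frequency bin (the
  achievable |AFD| shrinks with MAF, so percentiles must be taken among
  comparable sites);
* the two bulk comparisons, stratified by the unordered F0 parental genotype
  configuration (sites where the parents carry two copies of each allele can
  drift to large bulk differences by chance far more easily than 1:3 sites).

Within a stratum the p-value of a SNP is the inclusive upper-tail proportion
p = #{|AFD_j| >= |AFD_i|} / n — an empirical percentile, guaranteed > 0 and
conservative under ties.  The three p-values are multiplied into a combined
score, and combined-score thresholds are calibrated so that a stated number
m of SNPs (0.05, 1 or 5) would pass by chance among the N scored SNPs: under
independence the combined score of k uniform p-values has CDF
F_k(t) = t * sum_{i<k} (-ln t)^i / i!, and the threshold solves
N * F_k(t) = m.  An empirical-null calibration is provided for when the
same-sign pre-filter and stratification make exact uniformity approximate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import rankdata

from bsakit.afd import is_monomorphic_config

logger = logging.getLogger(__name__)

TIER_NAMES = {0.05: "fp0.05", 1.0: "fp1", 5.0: "fp5"}


# ----------------------------------------------------------------- strata


def maf_bins(
    maf: np.ndarray, bin_width: float = 0.05, min_bin: int = 200
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Assign each SNP a MAF stratum: fixed-width bins, merged to >= min_bin.

    Bins are [0, w), [w, 2w), ...; the last bin is right-closed so MAF = 0.5
    belongs to it.  Adjacent underfull bins are merged left-to-right until
    every stratum holds at least ``min_bin`` SNPs (or everything collapses
    into a single stratum).  Returns (bin index per SNP, bin edge list).
    """
    maf = np.asarray(maf, dtype=float)
    n_raw = int(np.ceil(0.5 / bin_width))
    raw = np.minimum((maf / bin_width).astype(int), n_raw - 1)
    counts = np.bincount(raw, minlength=n_raw)

    # merge greedily; then fold a trailing underfull group into its neighbour
    groups: list[list[int]] = []
    acc: list[int] = []
    acc_n = 0
    for b in range(n_raw):
        acc.append(b)
        acc_n += counts[b]
        if acc_n >= min_bin:
            groups.append(acc)
            acc, acc_n = [], 0
    if acc:
        if groups:
            groups[-1].extend(acc)
        else:
            groups.append(acc)
    mapping = np.empty(n_raw, dtype=int)
    for gi, bins_ in enumerate(groups):
        mapping[bins_] = gi
    edges = [
        (bins_[0] * bin_width, min((bins_[-1] + 1) * bin_width, 0.5))
        for bins_ in groups
    ]
    return mapping[raw], edges


# ---------------------------------------------------------- percentile p


def percentile_pvalues(values: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
    """Inclusive upper-tail empirical percentile of each value within its stratum.

    p_i = #{j in stratum(i): v_j >= v_i} / n_stratum; ties share the same p;
    the minimum value gets p = 1 and the unique maximum 1/n.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty stratum")
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    out = np.empty(len(values), dtype=float)
    df = pd.DataFrame({"v": values, "g": groups})
    for _, idx in df.groupby("g").groups.items():
        idx = np.asarray(idx)
        v = values[idx]
        # count of members >= v_i == n - (max rank of v_i counting ties) + ... :
        # rank with method='min' ascending gives #{< v_i} + 1; so
        # #{>= v_i} = n - rank_min + 1
        r = rankdata(v, method="min")
        out[idx] = (len(v) - r + 1) / len(v)
    return out


def combine_pvalues(p_pop, p_line1, p_line2):
    """Product of the three comparison p-values; inputs must lie in (0, 1]."""
    arrs = [np.asarray(p, dtype=float) for p in (p_pop, p_line1, p_line2)]
    for a in arrs:
        valid = np.isnan(a) | ((a > 0) & (a <= 1))
        if not np.all(valid):
            raise ValueError("p-values must lie in (0, 1]")
    return arrs[0] * arrs[1] * arrs[2]


# ---------------------------------------------------------- calibration


def product_uniform_cdf(t, k: int = 3):
    """CDF of the product of k independent Uniform(0,1): t * sum (-ln t)^i / i!."""
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("t must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        u = np.where(t > 0, -np.log(np.where(t > 0, t, 1.0)), np.inf)
    s = sum(u**i / math.factorial(i) for i in range(k))
    out = np.where(t > 0, t * s, 0.0)
    return out if out.ndim else float(out)


def fdr_threshold_analytic(m: float, n_snps: int, k: int = 3) -> float:
    """Combined-score threshold t with N * F_k(t) = m expected null passes."""
    if m <= 0:
        raise ValueError("m must be > 0")
    if n_snps < 1:
        raise ValueError("N must be >= 1")
    if m >= n_snps:
        logger.warning("m=%s >= N=%d: threshold saturates at 1", m, n_snps)
        return 1.0
    target = m / n_snps
    return float(
        brentq(lambda t: product_uniform_cdf(t, k) - target, 1e-300, 1.0, xtol=1e-16)
    )


def fdr_threshold_empirical(
    null_generator: Callable[[np.random.Generator, int], np.ndarray],
    m: float,
    n_snps: int,
    replicates: int,
    rng: np.random.Generator,
) -> float:
    """Threshold from simulated nulls: mean #{p_combined <= t} per replicate = m.

    ``null_generator(rng, N)`` must return one replicate's N combined null
    scores.  The threshold is the pooled order statistic at rank
    round(m * replicates).
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    k = int(round(m * replicates))
    if k < 1:
        needed = int(np.ceil(1.0 / m))
        logger.warning(
            "m=%s needs >= %d replicates for a resolvable threshold; got %d",
            m,
            needed,
            replicates,
        )
        k = 1
    pooled = np.concatenate(
        [np.asarray(null_generator(rng, n_snps), dtype=float) for _ in range(replicates)]
    )
    pooled.sort()
    t = float(pooled[k - 1])
    if t >= 1.0:
        logger.warning("degenerate null: empirical threshold saturates at 1")
    return t


# ---------------------------------------------------------- scoring


@dataclass
class SignificanceConfig:
    maf_bin_width: float = 0.05
    min_bin: int = 200
    fp_tiers: tuple[float, ...] = (0.05, 1.0, 5.0)
    afd_threshold: float = 0.5
    method: str = "analytic"  # or 'empirical'
    empirical_replicates: int = 200


@dataclass
class SignificanceResult:
    table: pd.DataFrame
    thresholds: dict[float, float]
    n_scored: int
    maf_bin_edges: list[tuple[float, float]] = field(default_factory=list)


def score_snps(
    afd_records: pd.DataFrame,
    config: SignificanceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SignificanceResult:
    """Score the same-sign SNP set: three p-values, combined score, tier.

    Expects the output of :func:`bsakit.afd.compute_afd` restricted to the
    same-sign set (rows failing ``same_sign`` are ignored with a warning).
    Sites whose parental configuration is missing are left unscored (NaN);
    sites monomorphic in the cross get line p-values of 1.
    """
    config = config or SignificanceConfig()
    df = afd_records.copy()
    if "same_sign" in df and not df["same_sign"].all():
        logger.warning("dropping %d non-concordant rows", int((~df["same_sign"]).sum()))
        df = df.loc[df["same_sign"]].copy()
    df = df.reset_index(drop=True)

    has_config = df["parental_config"].notna().to_numpy()
    scorable = has_config & df[["afd_pop", "afd_line1", "afd_line2", "maf"]].notna().all(
        axis=1
    ).to_numpy()
    n_scored = int(scorable.sum())
    sub = df.loc[scorable]

    bin_idx, edges = maf_bins(
        sub["maf"].to_numpy(), config.maf_bin_width, config.min_bin
    )
    p_pop = percentile_pvalues(sub["afd_pop"].abs().to_numpy(), bin_idx)

    mono = is_monomorphic_config(sub["parental_config"])
    p_lines = {}
    for comp in ("afd_line1", "afd_line2"):
        p = np.ones(len(sub), dtype=float)
        poly = ~mono
        if poly.any():
            configs = sub.loc[poly, "parental_config"].to_numpy()
            p[poly] = percentile_pvalues(
                sub.loc[poly, comp].abs().to_numpy(), configs
            )
        p_lines[comp] = p

    df["maf_bin"] = -1
    df.loc[scorable, "maf_bin"] = bin_idx
    df["p_pop"] = np.nan
    df["p_line1"] = np.nan
    df["p_line2"] = np.nan
    df.loc[scorable, "p_pop"] = p_pop
    df.loc[scorable, "p_line1"] = p_lines["afd_line1"]
    df.loc[scorable, "p_line2"] = p_lines["afd_line2"]
    df["p_combined"] = combine_pvalues(df["p_pop"], df["p_line1"], df["p_line2"])

    thresholds = calibrate_thresholds(config, n_scored, rng=rng)
    df["tier"] = classify_candidates(
        df["p_combined"].to_numpy(),
        thresholds,
        df["afd_pop"].abs().to_numpy() > config.afd_threshold,
    )
    return SignificanceResult(
        table=df, thresholds=thresholds, n_scored=n_scored, maf_bin_edges=edges
    )


def calibrate_thresholds(
    config: SignificanceConfig,
    n_scored: int,
    rng: np.random.Generator | None = None,
) -> dict[float, float]:
    """Combined-score threshold per expected-false-positive tier."""
    if n_scored < 1:
        return {m: 0.0 for m in config.fp_tiers}
    if config.method == "analytic":
        return {m: fdr_threshold_analytic(m, n_scored) for m in config.fp_tiers}
    if config.method == "empirical":
        rng = rng if rng is not None else np.random.default_rng(0)

        def null_gen(r: np.random.Generator, n: int) -> np.ndarray:
            return r.random((n, 3)).prod(axis=1)

        return {
            m: fdr_threshold_empirical(
                null_gen, m, n_scored, config.empirical_replicates, rng
            )
            for m in config.fp_tiers
        }
    raise ValueError(f"unknown calibration method {config.method!r}")


def classify_candidates(
    p_combined: np.ndarray,
    thresholds: dict[float, float],
    segregating: np.ndarray,
) -> np.ndarray:
    """Tier per SNP: smallest m whose threshold the combined score beats.

    Only SNPs in the segregating subset (|afd_pop| above the population AFD
    threshold) are eligible; everything else is 'none'.  Tiers are nested by
    construction since thresholds increase with m.
    """
    p = np.asarray(p_combined, dtype=float)
    tier = np.full(len(p), "none", dtype=object)
    for m in sorted(thresholds, reverse=True):
        name = TIER_NAMES.get(m, f"fp{m:g}")
        hit = segregating & ~np.isnan(p) & (p < thresholds[m])
        tier[hit] = name
    return tier
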