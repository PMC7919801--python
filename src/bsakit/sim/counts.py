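"""Pooled-RNAseq read counts for a bulk: negative-binomial depth, binomial split.

RNA from bulk members is pooled in equal amounts, so the expected reference
read fraction at a site is the mean reference-allele dosage over members
divided by two.  Per-site sequencing depth is negative binomial
(mean ``mean_depth``, gamma shape ``dispersion``; variance m + m^2/k).
"""

from __future__ import annotations

import numpy as np


def simulate_read_counts(
    member_dosages: np.ndarray,
    mean_depth: float,
    dispersion: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(ref_reads, alt_reads) per site for one bulk.

    Parameters
    ----------
    member_dosages : (n_sites, n_members) reference-allele dosages in {0,1,2}.
    mean_depth : mean per-site read depth (> 0; 0 is allowed and yields
        all-zero counts, which later fail the completeness filter).
    dispersion : negative-binomial shape k (larger = closer to Poisson).
    """
    if member_dosages.ndim != 2 or member_dosages.shape[1] == 0:
        raise ValueError("bulk must contain at least one member")
    n_sites = member_dosages.shape[0]
    if mean_depth <= 0:
        zeros = np.zeros(n_sites, dtype=np.int64)
        return zeros, zeros.copy()
    p_ref = member_dosages.mean(axis=1) / 2.0
    p_nb = dispersion / (dispersion + mean_depth)
    depth = rng.negative_binomial(dispersion, p_nb, size=n_sites)
    ref = rng.binomial(depth, p_ref)
    return ref.astype(np.int64), (depth - ref).astype(np.int64)
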