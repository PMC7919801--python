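"""Write a simulated study to disk: VCF + TSV mirror + ground-truth sidecar."""

from __future__ import annotations

import json
from pathlib import Path

from bsakit.sim.pipeline import StudyDesign, StudyResult


def emit_snp_table(
    result: StudyResult,
    outdir: str | Path,
    design: StudyDesign | None = None,
    prefix: str = "sim",
) -> dict[str, Path]:
    """Write ``<prefix>.vcf``, ``<prefix>.tsv`` and ``<prefix>.truth.json``.

    The truth sidecar records the configured QTLs, the master seed, realized
    bulk sizes and per-female diapause incidences.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}") from exc
    layout = design.layout if design is not None else None
    paths = {
        "vcf": outdir / f"{prefix}.vcf",
        "tsv": outdir / f"{prefix}.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    result.table.to_vcf(paths["vcf"], layout=layout)
    result.table.to_tsv(paths["tsv"])
    try:
        paths["truth"].write_text(json.dumps(result.truth, indent=2) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write truth sidecar {paths['truth']}: {exc}") from exc
    return paths
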