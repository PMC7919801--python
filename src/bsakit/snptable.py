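"""The pipeline's input container: biallelic SNPs with panel genotypes and bulk counts.

A :class:`SnpTable` holds, per site: (chrom, pos, ref, alt); reference-allele
dosages (0/1/2, -1 = missing) for every TEMP-panel and TROP-panel individual;
the F0 parental genotypes; and reference/alternate read counts for the four
pooled bulks (low/high diapause in each of two intercross lines).

Two interchange formats are supported: VCF 4.2 (panel genotypes as GT, bulk
pool counts as AD) and a flat TSV mirror whose column names are
self-describing (``temp:NAME``, ``trop:NAME``, ``parent_female``,
``bulk1_low_ref`` ...).  Sample-role metadata travels in a ``##bsakit_roles``
header line of the VCF, or in an explicit roles mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BULK_KEYS: tuple[tuple[int, str], ...] = (
    (1, "low"),
    (1, "high"),
    (2, "low"),
    (2, "high"),
)

_MISSING = -1


def _gt_string(dosage: int) -> str:
    return {2: "0/0", 1: "0/1", 0: "1/1"}.get(int(dosage), "./.")


@dataclass
class SnpTable:
    sites: pd.DataFrame  # columns chrom, pos, ref, alt
    temp_gt: np.ndarray  # (n_sites, n_temp) int8 dosages, -1 missing
    trop_gt: np.ndarray
    parent_female: np.ndarray  # (n_sites,) int8
    parent_male: np.ndarray
    bulk_counts: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]]
    temp_names: list[str] = field(default_factory=list)
    trop_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sites)
        if not self.temp_names:
            self.temp_names = [f"temp_{i+1:02d}" for i in range(self.temp_gt.shape[1])]
        if not self.trop_names:
            self.trop_names = [f"trop_{i+1:02d}" for i in range(self.trop_gt.shape[1])]
        for key in BULK_KEYS:
            if key not in self.bulk_counts:
                raise ValueError(f"missing bulk counts for {key}")
            ref, alt = self.bulk_counts[key]
            if len(ref) != n or len(alt) != n:
                raise ValueError(f"bulk {key}: count length mismatch")
            if np.any(ref < 0) or np.any(alt < 0):
                raise ValueError(f"bulk {key}: negative read counts")
        if self.temp_gt.shape != (n, len(self.temp_names)):
            raise ValueError("temp_gt shape mismatch")
        if self.trop_gt.shape != (n, len(self.trop_names)):
            raise ValueError("trop_gt shape mismatch")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate(self, layout=None) -> None:
        """Structural checks; optionally verify positions against a layout."""
        ref = self.sites["ref"].astype(str)
        alt = self.sites["alt"].astype(str)
        if (ref.str.len() != 1).any() or (alt.str.len() != 1).any():
            raise ValueError("non-biallelic-SNP alleles present")
        if (ref == alt).any():
            raise ValueError("ref == alt at some site")
        if layout is not None:
            for chrom, grp in self.sites.groupby("chrom"):
                L = layout[str(chrom)].physical_length
                if (grp["pos"] < 1).any() or (grp["pos"] > L).any():
                    raise ValueError(f"positions outside chromosome {chrom}")

    def subset(self, mask: np.ndarray) -> "SnpTable":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return SnpTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            temp_gt=self.temp_gt[idx],
            trop_gt=self.trop_gt[idx],
            parent_female=self.parent_female[idx],
            parent_male=self.parent_male[idx],
            bulk_counts={
                k: (r[idx].copy(), a[idx].copy())
                for k, (r, a) in self.bulk_counts.items()
            },
            temp_names=list(self.temp_names),
            trop_names=list(self.trop_names),
        )

    # ------------------------------------------------------------------ TSV

    def to_tsv(self, path: str | Path) -> None:
        df = self.sites.copy()
        for j, name in enumerate(self.temp_names):
            df[f"temp:{name}"] = self.temp_gt[:, j]
        for j, name in enumerate(self.trop_names):
            df[f"trop:{name}"] = self.trop_gt[:, j]
        df["parent_female"] = self.parent_female
        df["parent_male"] = self.parent_male
        for line, cls in BULK_KEYS:
            ref, alt = self.bulk_counts[(line, cls)]
            df[f"bulk{line}_{cls}_ref"] = ref
            df[f"bulk{line}_{cls}_alt"] = alt
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnpTable":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        except Exception as exc:  # surface path context
            raise IOError(f"cannot read SNP TSV {path}: {exc}") from exc
        temp_cols = [c for c in df.columns if c.startswith("temp:")]
        trop_cols = [c for c in df.columns if c.startswith("trop:")]
        bulk_counts = {}
        for line, cls_ in BULK_KEYS:
            bulk_counts[(line, cls_)] = (
                df[f"bulk{line}_{cls_}_ref"].to_numpy(np.int64),
                df[f"bulk{line}_{cls_}_alt"].to_numpy(np.int64),
            )
        return cls(
            sites=df[["chrom", "pos", "ref", "alt"]].copy(),
            temp_gt=df[temp_cols].to_numpy(np.int8),
            trop_gt=df[trop_cols].to_numpy(np.int8),
            parent_female=df["parent_female"].to_numpy(np.int8),
            parent_male=df["parent_male"].to_numpy(np.int8),
            bulk_counts=bulk_counts,
            temp_names=[c.split(":", 1)[1] for c in temp_cols],
            trop_names=[c.split(":", 1)[1] for c in trop_cols],
        )

    # ------------------------------------------------------------------ VCF

    def roles(self) -> dict:
        return {
            "temp": list(self.temp_names),
            "trop": list(self.trop_names),
            "parents": {"female": "F0_female", "male": "F0_male"},
            "bulks": {f"{line}:{cls}": f"bulk{line}_{cls}" for line, cls in BULK_KEYS},
        }

    def to_vcf(self, path: str | Path, layout=None) -> None:
        """Write VCF 4.2: GT for panel/parent samples, AD for bulk pools."""
        roles = self.roles()
        bulk_names = [roles["bulks"][f"{l}:{c}"] for l, c in BULK_KEYS]
        # panels may include the F0 parents by name; emit each sample once
        gt_columns: dict[str, np.ndarray] = {
            "F0_female": self.parent_female,
            "F0_male": self.parent_male,
        }
        for j, name in enumerate(self.temp_names):
            gt_columns.setdefault(name, self.temp_gt[:, j])
        for j, name in enumerate(self.trop_names):
            gt_columns.setdefault(name, self.trop_gt[:, j])
        samples = list(gt_columns) + bulk_names
        lines = [
            "##fileformat=VCFv4.2",
            "##source=bsakit",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
            f"##bsakit_roles={json.dumps(roles)}",
        ]
        if layout is not None:
            for c in layout:
                lines.append(f"##contig=<ID={c.id},length={c.physical_length}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
        sites = self.sites
        bulk_arrays = [self.bulk_counts[k] for k in BULK_KEYS]
        for i in range(self.n_sites):
            fields = [
                str(sites.at[i, "chrom"]),
                str(int(sites.at[i, "pos"])),
                ".",
                str(sites.at[i, "ref"]),
                str(sites.at[i, "alt"]),
                ".",
                "PASS",
                ".",
                "GT:AD",
            ]
            fields.extend(f"{_gt_string(col[i])}:." for col in gt_columns.values())
            fields.extend(
                f"./.:{int(ref[i])},{int(alt[i])}" for ref, alt in bulk_arrays
            )
            lines.append("\t".join(fields))
        try:
            Path(path).write_text("\n".join(lines) + "\n")
        except OSError as exc:
            raise IOError(f"cannot write VCF {path}: {exc}") from exc

    @classmethod
    def from_vcf(cls, path: str | Path, roles: dict | None = None) -> "SnpTable":
        """Read a VCF; sample roles come from ``roles`` or the bsakit header line."""
        from cyvcf2 import VCF

        try:
            vcf = VCF(str(path))
        except Exception as exc:
            raise IOError(f"cannot read VCF {path}: {exc}") from exc
        if roles is None:
            for raw in vcf.raw_header.splitlines():
                if raw.startswith("##bsakit_roles="):
                    roles = json.loads(raw.split("=", 1)[1])
                    break
            if roles is None:
                raise ValueError(
                    f"{path}: no ##bsakit_roles header; pass an explicit roles mapping"
                )
        samples = list(vcf.samples)
        col = {s: j for j, s in enumerate(samples)}
        temp_idx = [col[s] for s in roles["temp"]]
        trop_idx = [col[s] for s in roles["trop"]]
        pf_idx = col[roles["parents"]["female"]]
        pm_idx = col[roles["parents"]["male"]]
        bulk_idx = {
            key: col[roles["bulks"][f"{key[0]}:{key[1]}"]] for key in BULK_KEYS
        }

        rows = []
        dosages = []
        ads = []
        for v in vcf:
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                continue  # biallelic SNPs only
            rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
            gts = v.genotypes  # [a1, a2, phased] per sample
            dosages.append(
                [
                    _MISSING
                    if g[0] < 0
                    else int(g[0] == 0) + int(g[1] == 0)
                    for g in gts
                ]
            )
            ad = v.format("AD")
            ads.append(
                [
                    (max(int(ad[j, 0]), 0), max(int(ad[j, 1]), 0))
                    for j in bulk_idx.values()
                ]
            )
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        dos = np.array(dosages, dtype=np.int8).reshape(len(rows), len(samples))
        ad_arr = np.array(ads, dtype=np.int64).reshape(len(rows), len(BULK_KEYS), 2)
        bulk_counts = {
            key: (ad_arr[:, k, 0].copy(), ad_arr[:, k, 1].copy())
            for k, key in enumerate(BULK_KEYS)
        }
        return cls(
            sites=sites,
            temp_gt=dos[:, temp_idx],
            trop_gt=dos[:, trop_idx],
            parent_female=dos[:, pf_idx],
            parent_male=dos[:, pm_idx],
            bulk_counts=bulk_counts,
            temp_names=list(roles["temp"]),
            trop_names=list(roles["trop"]),
        )
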