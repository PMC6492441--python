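"""File I/O: minimal GT-only VCF 4.2, SSR tables, manifests, map TSVs.

Internal coordinates are 0-based half-open; VCF records are written
1-based and converted back on reading. VCF parsing goes through cyvcf2;
only biallelic SNVs are kept (multi-allelic records are skipped with a
logged reason, matching the biallelic filtering used upstream of this
kind of analysis).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix, SSRMarker, SSRTable
from .linkage_map import GeneticMap, RateProfile

logger = logging.getLogger(__name__)

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal VCF 4.2 with a GT FORMAT field only."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gm.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, pos in enumerate(gm.positions):
            calls = "\t".join(_GT_STRING[int(g)] for g in gm.genotypes[:, j])
            fh.write(f"{gm.chrom}\t{int(pos) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNV genotypes from a VCF into dosage form."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, rows, chrom = [], [], None
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        chrom = chrom or rec.CHROM
        positions.append(rec.POS - 1)
        gts = np.array([g[:2] for g in rec.genotypes], dtype=np.int16)
        dos = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        rows.append(dos.astype(np.int8))
    vcf.close()
    if skipped:
        logger.info("read_vcf skipped %d non-biallelic records", skipped)
    geno = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(
        samples=samples,
        positions=np.array(positions, dtype=np.int64),
        genotypes=geno,
        chrom=chrom or "chr25",
    )


def write_ssr_table(table: SSRTable, path: str | Path) -> Path:
    """SSR calls as TSV: marker, position_bp, then one len1/len2 column per progeny."""
    path = Path(path)
    rows = []
    for j, m in enumerate(table.markers):
        row = {"marker": m.id, "position_bp": m.position_bp}
        for i, prog in enumerate(table.progeny):
            l1, l2 = table.calls[i, j]
            row[prog] = "./." if l1 == MISSING or l2 == MISSING else f"{l1}/{l2}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_parent_alleles(markers: list[SSRMarker], path: str | Path) -> Path:
    """Parental haplotype assignment: marker -> a,b,c,d allele lengths."""
    pd.DataFrame(
        [
            {"marker": m.id, "position_bp": m.position_bp, "a": m.a, "b": m.b, "c": m.c, "d": m.d}
            for m in markers
        ]
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_ssr_table(calls_path: str | Path, parents_path: str | Path) -> SSRTable:
    """Read an SSR call table plus its parental-assignment file."""
    parents = pd.read_csv(parents_path, sep="\t")
    calls = pd.read_csv(calls_path, sep="\t")
    markers = []
    assign = {
        row["marker"]: row for _, row in parents.iterrows()
    }
    for _, row in calls.iterrows():
        mid = row["marker"]
        if mid not in assign:
            raise ValueError(f"marker {mid!r} missing from parental assignment file")
        p = assign[mid]
        markers.append(
            SSRMarker(
                id=mid,
                position_bp=int(row["position_bp"]),
                a=None if pd.isna(p["a"]) else int(p["a"]),
                b=None if pd.isna(p["b"]) else int(p["b"]),
                c=None if pd.isna(p["c"]) else int(p["c"]),
                d=None if pd.isna(p["d"]) else int(p["d"]),
            )
        )
    progeny = [c for c in calls.columns if c not in ("marker", "position_bp")]
    arr = np.full((len(progeny), len(markers), 2), MISSING, dtype=np.int32)
    for j in range(len(markers)):
        for i, prog in enumerate(progeny):
            val = str(calls.iloc[j][prog])
            if "/" in val and "." not in val:
                l1, l2 = val.split("/")
                arr[i, j] = (int(l1), int(l2))
    return SSRTable(markers=markers, progeny=progeny, calls=arr)


def write_map(gmap: GeneticMap, path: str | Path) -> Path:
    """Genetic map TSV: marker, bp, adjacent r, interval cM, cumulative cM."""
    rows = []
    for k in range(gmap.n_markers):
        rows.append(
            {
                "marker": gmap.marker_ids[k],
                "position_bp": int(gmap.positions[k]),
                "r_prev": np.nan if k == 0 else gmap.r[k - 1],
                "interval_cm": 0.0 if k == 0 else gmap.interval_cm[k - 1],
                "cum_cm": gmap.cum_cm[k],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return Path(path)


def write_rate_profile(profile: RateProfile, path: str | Path) -> Path:
    """Rate profile as BED-like TSV (start, end, cM/Mb)."""
    pd.DataFrame(
        {
            "window_start": profile.window_start,
            "window_end": profile.window_end,
            "cm_per_mb": profile.cm_per_mb,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    return Path(path)


def write_sex_manifest(sexes: dict[str, str], path: str | Path) -> Path:
    pd.DataFrame(sorted(sexes.items()), columns=["sample", "sex"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_sex_manifest(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["sex"]))
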