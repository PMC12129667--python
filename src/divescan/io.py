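"""File input/output: VCF genotypes and the tabular interchange formats.

VCF is written as plain text (v4.2, GT-only biallelic records) and read
through cyvcf2. Population labels travel in a separate two-column sample
table; phenotypes, scan tables and candidate lists are tab-separated files.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write biallelic GT-only records as uncompressed VCF v4.2."""
    var = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divescan\n")
        for chrom in dict.fromkeys(var["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        calls = genotypes.calls
        for j in range(genotypes.n_variants):
            row = var.iloc[j]
            gts = "\t".join(_GT_STRING[int(g)] for g in calls[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | os.PathLike,
    sample_table: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF.

    ``sample_table`` (columns ``sample_id``, ``population``) supplies
    population labels; samples absent from it get population ``"unknown"``.
    Multiallelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows = []
    cols = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}; biallelic input required")
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        types = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dosage = np.select(
            [types == 0, types == 1, types == 3], [0, 1, 2], default=MISSING
        ).astype(np.int8)
        cols.append(dosage)
    vcf.close()
    if not rows:
        raise ValueError("no variant records in VCF")
    calls = np.stack(cols, axis=1)
    variants = pd.DataFrame(rows)
    if sample_table is not None:
        pop_map = dict(zip(sample_table["sample_id"], sample_table["population"]))
    else:
        pop_map = {}
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": [pop_map.get(s, "unknown") for s in sample_ids],
        }
    )
    return GenotypeMatrix(calls=calls, samples=samples, variants=variants)


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    """Two-column TSV: sample_id, population."""
    table = pd.read_csv(path, sep="\t")
    if "sample_id" not in table.columns or "population" not in table.columns:
        raise ValueError("sample table needs 'sample_id' and 'population' columns")
    return table


def write_phenotypes(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "phenotype"):
        if col not in table.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    return table


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_scan_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("id", "chrom", "pos", "llr"):
        if col not in table.columns:
            raise ValueError(f"scan table lacks column {col!r}")
    return table


def write_bed(peaks: Sequence, path: str | os.PathLike) -> None:
    """Peaks as BED (0-based half-open conversion at write time)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.top_snp}\t{p.top_llr:.6g}\n")
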