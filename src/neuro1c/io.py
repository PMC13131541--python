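"""Plain-text readers and writers for the pipeline tables.

Subject tables, raw assays, processed matrices and association tables travel
as TSV; genotypes as TSV (rows = subjects, columns = SNP ids, values 0/1/2,
"." missing) or as a minimal unphased VCF (GT field only).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_tsv(df: pd.DataFrame, path, *, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_assay(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    out = genotypes.copy()
    out = out.map(lambda v: "." if pd.isna(v) else str(int(v)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=True)


def read_genotypes_tsv(path) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return g.map(lambda v: np.nan if v in (".", "", "nan") else float(v))


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(genotypes: pd.DataFrame, path) -> None:
    """Minimal VCFv4.2 with placeholder coordinates and GT-only FORMAT;
    rows are SNPs in column order, samples are the genotype-table index."""
    samples = list(genotypes.index)
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(samples)]
    for i, snp in enumerate(genotypes.columns, start=1):
        calls = ["./." if pd.isna(v) else _GT[int(v)]
                 for v in genotypes[snp].to_numpy(float)]
        lines.append(f"1\t{i}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Read GT calls from a VCF into a subjects x SNPs allele-count table."""
    samples: list[str] = []
    data: dict[str, list[float]] = {}
    ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if line.startswith("#CHROM"):
            samples = fields[9:]
            continue
        snp = fields[2]
        ids.append(snp)
        fmt = fields[8].split(":")
        gt_idx = fmt.index("GT")
        counts = []
        for cell in fields[9:]:
            gt = cell.split(":")[gt_idx].replace("|", "/")
            if "." in gt:
                counts.append(np.nan)
            else:
                counts.append(float(sum(int(x) > 0 for x in gt.split("/"))))
        data[snp] = counts
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"),
                        columns=ids)
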