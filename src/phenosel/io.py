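"""Readers and writers for the pipeline's interchange files.

Genotypes travel as lines x markers CSV (header row of marker ids) or as a
minimal VCF dialect in which pooled dosages are stored in a per-sample DS
field (GT is emitted as the rounded hard call for interoperability). Plot
tables, trait panels, BLUEs and simulation truth are plain CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import GeneticMap, MarkerMatrix

__all__ = [
    "write_genotypes_csv",
    "read_genotypes_csv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "read_genotypes",
    "write_table",
    "read_table",
]

FLOAT_FMT = "%.10g"


def write_genotypes_csv(matrix: MarkerMatrix, path) -> None:
    matrix.dosages.to_csv(path, index_label="line", float_format=FLOAT_FMT)


def read_genotypes_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col="line").rename_axis(index=None).astype(float)
    return MarkerMatrix(df)


def write_genotypes_vcf(matrix: MarkerMatrix, path) -> None:
    """Minimal uncompressed VCF 4.2 with DS (dosage) per sample.

    Map positions (cM) are scaled to integer coordinates (1 cM = 10,000 bp
    equivalents) purely to obtain valid POS values.
    """
    dos = matrix.dosages
    gmap = matrix.map
    lines = list(dos.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Rounded call">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Pooled dosage">\n')
        if gmap is not None:
            for cid, ln in gmap.chromosomes:
                fh.write(f"##contig=<ID={cid},length={int(ln * 10000) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(lines) + "\n")
        for j, mid in enumerate(dos.columns):
            if gmap is not None:
                chrom = gmap.chromosomes[gmap.marker_chrom[j]][0]
                pos = int(round(gmap.marker_pos[j] * 10000)) + 1
            else:
                chrom, pos = "1", j + 1
            fields = [chrom, str(pos), str(mid), "A", "B", ".", "PASS", ".", "GT:DS"]
            for v in dos[mid].to_numpy():
                if np.isnan(v):
                    fields.append("./.:.")
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(round(min(max(v, 0), 2)))]
                    fields.append(f"{gt}:{v:.6g}")
            fh.write("\t".join(fields) + "\n")


def read_genotypes_vcf(path) -> MarkerMatrix:
    """Read the minimal VCF dialect back into a MarkerMatrix (DS field)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for var in vcf:
        ids.append(var.ID)
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        cols.append(ds)
    vcf.close()
    df = pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)
    df[df < 0] = np.nan  # cyvcf2 missing sentinel
    return MarkerMatrix(df)


def read_genotypes(path) -> MarkerMatrix:
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return read_genotypes_vcf(path)
    return read_genotypes_csv(path)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
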