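"""Readers and writers for the plain-text formats the pipeline consumes.

BED6 for interval tracks (feature class in the name field), FASTA for
genomes and DMR sequences, VCF 4.2 for genotypes, TSV for sample sheets
and result tables, and a minimal MEME-format motif file.
"""

from __future__ import annotations

import os
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import BED_COLUMNS


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into an interval frame (missing columns filled)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, fill in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = fill
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(genotypes: pd.DataFrame, dosages: np.ndarray, sample_ids, path,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT fields from alt-allele dosages (0/1/2, -1 missing)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, sample_ids)) + "\n")
        for i, row in enumerate(genotypes.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in dosages[i])
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read a VCF into (genotype frame, dosage matrix, sample ids) via pysam."""
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    rows, dos = [], []
    for rec in vf:
        rows.append((rec.id, rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
        row = []
        for s in sample_ids:
            gt = rec.samples[s]["GT"]
            row.append(-1 if gt is None or gt[0] is None else int(sum(gt)))
        dos.append(row)
    frame = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return frame, np.asarray(dos, dtype=int), sample_ids


def write_meme_motif(pwm, path, name: str = "MOTIF_1") -> None:
    """Write a PWM in minimal MEME text format (version, alphabet, background, matrix)."""
    bg = pwm.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20\n")
        for col in pwm.probabilities.T:
            fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")


def read_meme_motif(path):
    """Read the first motif from a minimal MEME text file."""
    from .motifs import PWM

    background = np.full(4, 0.25)
    matrix_rows = []
    in_matrix = False
    with open(path) as fh:
        lines = iter(fh.readlines())
        for line in lines:
            line = line.strip()
            if line.startswith("Background letter frequencies"):
                parts = next(lines).split()
                background = np.array([float(parts[i]) for i in (1, 3, 5, 7)])
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                if not line:
                    break
                matrix_rows.append([float(x) for x in line.split()])
    probs = np.asarray(matrix_rows).T  # 4 x width
    return PWM(probabilities=probs, background=background)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
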