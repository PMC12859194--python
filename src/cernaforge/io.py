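"""Writers and readers for the standard text formats the pipeline exchanges.

Coordinates are 0-based half-open internally (BED native); the GTF writer
converts to 1-based inclusive on output.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    """Write an ordered mapping id->sequence as FASTA (order preserved)."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gtf(models: pd.DataFrame, path: str | os.PathLike, source: str = "cernaforge") -> None:
    """Write gene models (one row per gene, exon_starts/exon_ends lists of
    0-based half-open intervals) as GTF gene + exon records (1-based inclusive)."""
    with open(path, "w") as fh:
        for row in models.itertuples():
            attrs = f'gene_id "{row.gene_id}";'
            tx_start = min(row.exon_starts)
            tx_end = max(row.exon_ends)
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{tx_start + 1}\t{tx_end}\t.\t{row.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(zip(row.exon_starts, row.exon_ends), start=1):
                fh.write(
                    f"{row.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{row.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def write_bed12(models: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene models as BED12 (native 0-based half-open)."""
    with open(path, "w") as fh:
        for row in models.itertuples():
            starts = list(row.exon_starts)
            ends = list(row.exon_ends)
            chrom_start = starts[0]
            chrom_end = ends[-1]
            sizes = ",".join(str(e - s) for s, e in zip(starts, ends)) + ","
            offsets = ",".join(str(s - chrom_start) for s in starts) + ","
            fh.write(
                f"{row.chrom}\t{chrom_start}\t{chrom_end}\t{row.gene_id}\t0\t{row.strand}\t"
                f"{chrom_start}\t{chrom_end}\t0\t{len(starts)}\t{sizes}\t{offsets}\n"
            )


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write(name + "\t" + name + "\t" + "\t".join(genes) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    """Deterministic TSV output: fixed float format, LF line endings."""
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.10g")


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(design.columns):
        raise ValueError("design table requires 'sample' and 'group' columns")
    return design
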