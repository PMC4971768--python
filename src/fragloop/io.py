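"""Readers and writers for the plain-text formats the pipeline consumes.

Internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted here at the boundary.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneModel, GenomeSegment, SegmentUniverse

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genes_gff3",
    "write_genes_gff3",
    "read_genes_bed12",
    "read_pairs",
    "write_pairs",
    "read_contacts_bedpe",
    "write_contacts_bedpe",
    "write_segments_bed",
    "read_bed",
    "write_bed",
]


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_genes_gff3(path: str) -> List[GeneModel]:
    """Genes from GFF3 'gene' features; expression from an
    'expression_level=' attribute when present."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            start, end = start1 - 1, end1  # to 0-based half-open
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = fields.get("ID", f"{chrom}:{start}-{end}")
            level = fields.get("expression_level")
            tss, tts = (start, end) if strand == "+" else (end, start)
            genes.append(
                GeneModel(
                    id=gid, chrom=chrom, strand=strand, tss=tss, tts=tts,
                    expression_level=int(level) if level is not None else None,
                )
            )
    return genes


def write_genes_gff3(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            if g.expression_level is not None:
                attrs += f";expression_level={g.expression_level}"
            fh.write(
                "\t".join(
                    [
                        g.chrom, "fragloop", "gene",
                        str(g.body_start + 1), str(g.body_end),
                        ".", g.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def read_genes_bed12(path: str) -> List[GeneModel]:
    """Genes from BED12 (chrom, start, end, name, score, strand, ...)."""
    genes = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for _, r in df.iterrows():
        chrom, start, end, name, strand = r[0], int(r[1]), int(r[2]), str(r[3]), r[5]
        tss, tts = (start, end) if strand == "+" else (end, start)
        genes.append(GeneModel(id=name, chrom=chrom, strand=strand, tss=tss, tts=tts))
    return genes


PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


def read_pairs(path: str) -> pd.DataFrame:
    """6-column mate-pair text (tab-separated, '#' comments); strand
    columns are accepted and ignored downstream. A 5-column file is read
    as pre-aggregated segment-pair counts (chrom, seg_a, seg_b, count,
    distance)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] >= 6:
        df = df.iloc[:, :6]
        df.columns = PAIR_COLUMNS
        return df
    if df.shape[1] == 5:
        df.columns = ["chrom", "seg_a", "seg_b", "count", "distance"]
        return df
    raise ValueError(f"unrecognized pairs dialect with {df.shape[1]} columns")


def write_pairs(pairs: pd.DataFrame, path: str) -> None:
    pairs.to_csv(path, sep="\t", header=False, index=False)


def write_contacts_bedpe(
    contacts: pd.DataFrame, universe: SegmentUniverse, path: str
) -> None:
    """BEDPE-like TSV: chrom a_start a_end chrom b_start b_end count distance."""
    ra = universe.row(contacts["seg_a"].to_numpy())
    rb = universe.row(contacts["seg_b"].to_numpy())
    out = pd.DataFrame(
        {
            "chrom_a": universe.chrom[ra],
            "start_a": universe.start[ra],
            "end_a": universe.end[ra],
            "chrom_b": universe.chrom[rb],
            "start_b": universe.start[rb],
            "end_b": universe.end[rb],
            "count": contacts["count"],
            "distance": contacts["distance"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_contacts_bedpe(path: str, universe: SegmentUniverse) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    seg_a = np.empty(len(df), dtype=np.int64)
    seg_b = np.empty(len(df), dtype=np.int64)
    for i, r in df.iterrows():
        seg_a[i] = universe.locate(str(r["chrom_a"]), np.array([int(r["start_a"])]))[0]
        seg_b[i] = universe.locate(str(r["chrom_b"]), np.array([int(r["start_b"])]))[0]
    return pd.DataFrame(
        {
            "seg_a": seg_a,
            "seg_b": seg_b,
            "count": df["count"].to_numpy(),
            "distance": df["distance"].to_numpy(),
        }
    )


def write_segments_bed(segments: Sequence[GenomeSegment], path: str) -> None:
    """BED4: chrom, start, end, id."""
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.id}\n")


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_bed(track: pd.DataFrame, path: str) -> None:
    track[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )
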