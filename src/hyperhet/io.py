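"""Readers and writers for the plain-text formats used across the pipeline.

FASTA/FASTQ go through Biopython; GFF3 is a controlled subset
(gene/mRNA/exon/CDS with ID/Parent attributes) read into GeneModel
records; tables are TSV via pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -- sequence encoding helpers (A=0, C=1, G=2, T=3, anything else = 255) --

_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _ENCODE[ord(base)] = i
    _ENCODE[ord(base.lower())] = i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (N and friends become 255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    if np.any(codes > 3):
        out = np.full(codes.shape, ord("N"), dtype=np.uint8)
        ok = codes <= 3
        out[ok] = _DECODE[codes[ok]]
        return out.tobytes().decode("ascii")
    return _DECODE[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------- FASTA --

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- FASTQ --

def write_fastq(reads: list[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs with a flat Phred+33 quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ----------------------------------------------------------------- GFF3 --

@dataclass
class GeneModel:
    """One gene on one haplotype scaffold; intervals 0-based half-open."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    haplotype: str = "A"
    allelic_partner: str | None = None

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        exons = sorted(self.exons)
        if exons != self.exons:
            raise ValueError(f"exons not sorted for {self.gene_id}")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        cds_len = sum(e - s for s, e in self.cds_intervals)
        if cds_len % 3 != 0:
            raise ValueError(f"CDS length {cds_len} not multiple of 3 in {self.gene_id}")
        for cs, ce in self.cds_intervals:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"CDS interval outside exons in {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def shifted(self, mapper) -> "GeneModel":
        """New model with every coordinate passed through ``mapper``.

        ``mapper`` maps base positions; interval ends are mapped as
        (last base + 1) so that insertions exactly at an interval end stay
        outside it.
        """
        def iv(s: int, e: int) -> tuple[int, int]:
            return mapper(s), mapper(e - 1) + 1

        return GeneModel(
            gene_id=self.gene_id,
            scaffold=self.scaffold,
            strand=self.strand,
            exons=[iv(s, e) for s, e in self.exons],
            cds_intervals=[iv(s, e) for s, e in self.cds_intervals],
            haplotype=self.haplotype,
            allelic_partner=self.allelic_partner,
        )


def write_gff3(genes: list[GeneModel], path) -> None:
    """GFF3 (1-based inclusive) with gene/mRNA/exon/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            attrs = f"ID={g.gene_id}"
            if g.allelic_partner:
                attrs += f";allelic_partner={g.allelic_partner}"
            attrs += f";haplotype={g.haplotype}"
            fh.write(
                f"{g.scaffold}\thyperhet\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.scaffold}\thyperhet\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for xs, xe in g.exons:
                fh.write(
                    f"{g.scaffold}\thyperhet\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"Parent={mrna}\n"
                )
            for cs, ce in g.cds_intervals:
                fh.write(
                    f"{g.scaffold}\thyperhet\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                    f"Parent={mrna}\n"
                )


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out


def read_gff3(path) -> pd.DataFrame:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols, dtype={"start": int, "end": int})
    return df


def read_gff_genes(path) -> list[GeneModel]:
    """Reconstruct GeneModel records from a GFF3 written by this package."""
    df = read_gff3(path)
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    for row in df.itertuples(index=False):
        attrs = _parse_attrs(row.attributes)
        if row.type == "gene":
            genes[attrs["ID"]] = GeneModel(
                gene_id=attrs["ID"],
                scaffold=row.seqid,
                strand=row.strand,
                exons=[],
                cds_intervals=[],
                haplotype=attrs.get("haplotype", "A"),
                allelic_partner=attrs.get("allelic_partner") or None,
            )
        elif row.type == "mRNA":
            mrna_to_gene[attrs["ID"]] = attrs["Parent"]
        elif row.type in ("exon", "CDS"):
            gene = genes[mrna_to_gene[attrs["Parent"]]]
            iv = (row.start - 1, row.end)
            if row.type == "exon":
                gene.exons.append(iv)
            else:
                gene.cds_intervals.append(iv)
    for gene in genes.values():
        gene.exons.sort()
        gene.cds_intervals.sort()
    return list(genes.values())


# ------------------------------------------------------------------ TSV --

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
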