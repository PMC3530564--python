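"""File I/O helpers: FASTA/FASTQ via Biopython, BED and TSV writers.

All genomic intervals written or read here are 0-based, half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import CleanTag, LibraryQCReport

__all__ = [
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "write_collapsed_tags",
    "read_collapsed_tags",
    "write_bed6",
    "write_qc_report",
]


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (description, sequence) from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.description, str(rec.seq)


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from a Sanger-encoded FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    recs = (
        SeqRecord(Seq(seq), id=name.split()[0], description=name)
        for name, seq in records
    )
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_collapsed_tags(path, tags: Iterable[CleanTag]) -> None:
    """Collapsed-tag FASTA with the conventional '>tag_<i>_x<count>' headers."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag_{i}_x{tag.count}\n{tag.sequence}\n")


def read_collapsed_tags(path) -> list[CleanTag]:
    tags = []
    for name, seq in read_fasta(path):
        count = int(name.split()[0].rsplit("_x", 1)[1])
        tags.append(CleanTag(seq, count))
    return tags


def write_bed6(path, rows: Iterable[tuple[str, int, int, str, int, str]]) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_qc_report(path, report: LibraryQCReport) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\tpercent_of_raw\n")
        for row, count, pct in report.as_rows():
            fh.write(f"{row}\t{count}\t{pct:.2f}\n")
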