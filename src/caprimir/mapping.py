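"""Exhaustive short-tag genome mapping with at most one mismatch.

Seed-and-verify mapper in the SOAP small-RNA spirit: substitutions only, no
indels, and *every* genomic locus within Hamming distance 1 is reported, on
both strands.  Completeness follows from the pigeonhole principle: with at
most one mismatch, at least one of the tag's two halves matches exactly, so
looking up a seed at the start of each half finds every hit.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, NamedTuple

__all__ = [
    "Alignment",
    "GenomeIndex",
    "build_index",
    "map_tag",
    "classify_mapping",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Alignment(NamedTuple):
    """One genomic hit of a tag; ``start`` is 0-based, end-exclusive span
    is ``start + len(tag)``."""

    chrom: str
    start: int
    strand: str
    mismatches: int


class GenomeIndex:
    """k-mer position index over the plus strand of each chromosome.

    Queries are run for the tag and its reverse complement, so both
    orientations are covered without indexing the reverse strand.
    """

    def __init__(self, sequences: dict[str, str], k: int = 9):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.k = k
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.kmer_index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.sequences.items():
            for pos in range(len(seq) - k + 1):
                self.kmer_index[seq[pos : pos + k]].append((name, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        if len(kmer) != self.k:
            raise ValueError("query length must equal the index k")
        return self.kmer_index.get(kmer, [])


def build_index(sequences: dict[str, str], k: int = 9) -> GenomeIndex:
    """Build a :class:`GenomeIndex` from named chromosome sequences."""
    return GenomeIndex(sequences, k=k)


def _hamming_le1(a: str, b: str) -> int:
    """Mismatch count if <= 1, else -1 (early exit)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > 1:
                return -1
    return mm


def map_tag(tag: str, index: GenomeIndex, max_mismatch: int = 1) -> list[Alignment]:
    """All loci of ``tag`` in the genome with at most one mismatch.

    Each (chrom, start, strand) is reported once; a palindromic locus hit on
    both strands yields two alignments at the same (chrom, start).
    """
    tag = tag.upper()
    if len(tag) < 18:
        raise ValueError("tags shorter than 18 nt are not mappable here")
    if set(tag) - set("ACGT"):
        raise ValueError("tag contains non-ACGT characters")
    if max_mismatch not in (0, 1):
        raise ValueError("only 0 or 1 mismatches supported")
    k = index.k
    half = len(tag) // 2
    if k > half:
        raise ValueError(f"index seed k={k} too long for tag length {len(tag)}")

    hits: dict[tuple[str, int, str], int] = {}
    for strand, query in (("+", tag), ("-", reverse_complement(tag))):
        seen: set[tuple[str, int]] = set()
        for offset in (0, half):
            seed = query[offset : offset + k]
            for chrom, pos in index.lookup(seed):
                start = pos - offset
                if start < 0 or (chrom, start) in seen:
                    continue
                seen.add((chrom, start))
                ref = index.sequences[chrom]
                if start + len(query) > len(ref):
                    continue
                mm = _hamming_le1(query, ref[start : start + len(query)])
                if 0 <= mm <= max_mismatch:
                    hits[(chrom, start, strand)] = mm
    return sorted(
        Alignment(c, s, st, mm) for (c, s, st), mm in hits.items()
    )


def classify_mapping(alignments: Iterable[Alignment]) -> tuple[str, int]:
    """(status, n_loci): 'unmapped', 'unique' or 'multi'.

    Loci are distinct (chrom, start) positions -- a palindromic both-strand
    hit at one position still counts as a single locus.
    """
    loci = {(a.chrom, a.start) for a in alignments}
    if not loci:
        return ("unmapped", 0)
    if len(loci) == 1:
        return ("unique", 1)
    return ("multi", len(loci))
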