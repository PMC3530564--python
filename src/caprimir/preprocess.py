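"""Raw-read cleaning, tag collapsing and library QC accounting.

A raw small-RNA read is the 18-30 nt insert followed by the 3' sequencing
adapter (and, for short inserts, whatever lies beyond it).  Cleaning walks a
fixed category ladder; each read lands in exactly the first category it
matches:

1. ``low_quality``            -- contains an N (the only quality signal kept)
2. ``adapter3_null``          -- no >=6 nt prefix of the 3' adapter anywhere,
                                 or the implied insert is longer than 30 nt
3. ``insert_null``            -- the adapter starts at position 0
4. ``adapter5_contaminant``   -- the insert begins with the tail of the
                                 5' adapter
5. ``polyA``                  -- the insert is >= 80% A
6. ``too_short``              -- the insert is shorter than 18 nt
7. ``clean``                  -- everything else; the trimmed insert survives

Clean inserts are collapsed into unique tags with read counts, and the
category tallies form the library QC report (counts and percentages of raw
reads).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

__all__ = [
    "CleanTag",
    "LibraryQCReport",
    "ReadCategory",
    "classify_read",
    "clean_library",
    "length_distribution",
    "starts_with_adapter5_suffix",
    "MIN_INSERT",
    "MAX_INSERT",
    "MIN_ADAPTER_OVERLAP",
    "POLYA_FRACTION",
]

MIN_INSERT = 18
MAX_INSERT = 30
MIN_ADAPTER_OVERLAP = 6
POLYA_FRACTION = 0.8

ARTIFACT_CATEGORIES = (
    "low_quality",
    "adapter3_null",
    "insert_null",
    "adapter5_contaminant",
    "polyA",
    "too_short",
)


class CleanTag(NamedTuple):
    """A unique clean insert sequence with its library read count."""

    sequence: str
    count: int


class ReadCategory(NamedTuple):
    category: str
    insert: str | None  # trimmed insert for clean reads, else None


@dataclass
class LibraryQCReport:
    """Per-category cleaning accounting for one library.

    ``clean_reads`` always equals ``high_quality`` minus the artifact
    categories; percentages use raw reads as the denominator.
    """

    raw_reads: int = 0
    high_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminant: int = 0
    shorter_than_18: int = 0
    polyA: int = 0
    clean_reads: int = 0

    ROW_ORDER = (
        "raw_reads",
        "high_quality",
        "adapter3_null",
        "insert_null",
        "adapter5_contaminant",
        "shorter_than_18",
        "polyA",
        "clean_reads",
    )

    def percentage(self, row: str) -> float:
        if self.raw_reads == 0:
            return 0.0
        return 100.0 * getattr(self, row) / self.raw_reads

    def check_identity(self) -> None:
        expect = self.high_quality - (
            self.adapter3_null
            + self.insert_null
            + self.adapter5_contaminant
            + self.shorter_than_18
            + self.polyA
        )
        if expect != self.clean_reads:
            raise AssertionError("QC accounting identity violated")

    def as_rows(self) -> list[tuple[str, int, float]]:
        return [(r, getattr(self, r), self.percentage(r)) for r in self.ROW_ORDER]


def starts_with_adapter5_suffix(
    insert: str, adapter_5p: str, min_overlap: int = MIN_ADAPTER_OVERLAP
) -> bool:
    """True when the insert begins with a >= ``min_overlap`` nt suffix of the
    5' adapter (the read-through signature of a 5'-adapter contaminant)."""
    a5 = adapter_5p.upper()
    for k in range(min(len(a5), len(insert)), min_overlap - 1, -1):
        if insert.startswith(a5[-k:]):
            return True
    return False


def _find_adapter(sequence: str, adapter: str, min_overlap: int) -> int | None:
    """Leftmost start of the longest matching adapter prefix, or None.

    Tries the full adapter first, then successively shorter prefixes down to
    ``min_overlap`` nt, so a genuine full-length adapter hit always beats a
    chance short match further left.
    """
    max_len = min(len(adapter), len(sequence))
    for ln in range(max_len, min_overlap - 1, -1):
        pos = sequence.find(adapter[:ln])
        if pos != -1:
            return pos
    return None


def classify_read(
    sequence: str,
    adapter_3p: str,
    adapter_5p: str,
    *,
    min_insert: int = MIN_INSERT,
    max_insert: int = MAX_INSERT,
    min_overlap: int = MIN_ADAPTER_OVERLAP,
    polya_fraction: float = POLYA_FRACTION,
) -> ReadCategory:
    """Assign a raw read to its cleaning category (first match wins)."""
    if not sequence:
        raise ValueError("empty read sequence")
    if not adapter_3p or not adapter_5p:
        raise ValueError("adapters must be non-empty")
    seq = sequence.upper()
    if "N" in seq:
        return ReadCategory("low_quality", None)
    pos = _find_adapter(seq, adapter_3p.upper(), min_overlap)
    if pos is None or pos > max_insert:
        return ReadCategory("adapter3_null", None)
    if pos == 0:
        return ReadCategory("insert_null", None)
    insert = seq[:pos]
    if starts_with_adapter5_suffix(insert, adapter_5p, min_overlap):
        return ReadCategory("adapter5_contaminant", None)
    if insert.count("A") / len(insert) >= polya_fraction:
        return ReadCategory("polyA", None)
    if len(insert) < min_insert:
        return ReadCategory("too_short", None)
    return ReadCategory("clean", insert)


def clean_library(
    reads: Iterable[tuple[str, str]],
    adapter_3p: str,
    adapter_5p: str,
    **kwargs,
) -> tuple[list[CleanTag], LibraryQCReport]:
    """Classify a read stream, collapse clean inserts to unique tags.

    Parameters
    ----------
    reads:
        Iterable of ``(read_id, sequence)`` pairs (see :mod:`caprimir.io`).

    Returns
    -------
    (tags, report)
        Tags sorted by descending count then sequence; counts are conserved
        (sum of tag counts equals ``report.clean_reads``).
    """
    counts: Counter[str] = Counter()
    report = LibraryQCReport()
    low_quality = 0
    for idx, item in enumerate(reads):
        try:
            _read_id, seq = item
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unreadable read record at index {idx}") from exc
        cat, insert = classify_read(seq, adapter_3p, adapter_5p, **kwargs)
        report.raw_reads += 1
        if cat == "low_quality":
            low_quality += 1
        elif cat == "adapter3_null":
            report.adapter3_null += 1
        elif cat == "insert_null":
            report.insert_null += 1
        elif cat == "adapter5_contaminant":
            report.adapter5_contaminant += 1
        elif cat == "polyA":
            report.polyA += 1
        elif cat == "too_short":
            report.shorter_than_18 += 1
        else:
            report.clean_reads += 1
            counts[insert] += 1
    report.high_quality = report.raw_reads - low_quality
    report.check_identity()
    tags = [CleanTag(s, c) for s, c in counts.items()]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags, report


def length_distribution(tags: Iterable[CleanTag]) -> dict[int, int]:
    """Read counts by insert length (reads, not unique tags)."""
    hist: Counter[int] = Counter()
    for tag in tags:
        hist[len(tag.sequence)] += tag.count
    return dict(sorted(hist.items()))
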