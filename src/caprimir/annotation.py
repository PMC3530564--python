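"""Hierarchical annotation of mapped tags into small-RNA categories.

Each tag receives exactly one category by fixed priority:

    known_miRNA > rRNA > tRNA > snRNA > snoRNA > scRNA > srpRNA
                > repeat > exon > intron > unannotated

Known-miRNA status comes from the reference-matching module; the remaining
classes come from strand-agnostic interval overlap (any aligned base inside a
feature interval, at any of the tag's alignments) against a labelled feature
set.  This replaces sequence-similarity triage against ncRNA databases with a
deterministic positional lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .mapping import Alignment

__all__ = [
    "PRIORITY",
    "NCRNA_CLASSES",
    "Feature",
    "FeatureSet",
    "annotate_tag",
    "summarize_categories",
]

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA", "srpRNA")

#: category priority, highest first
PRIORITY = (
    "known_miRNA",
    *NCRNA_CLASSES,
    "repeat",
    "exon",
    "intron",
    "unannotated",
)

_RANK = {cat: i for i, cat in enumerate(PRIORITY)}
FEATURE_CLASSES = frozenset(PRIORITY[1:-1])


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.cls!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid feature coordinates")


class FeatureSet:
    """Interval-indexed collection of labelled genomic features."""

    def __init__(self, features: Iterable[Feature] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self.features: list[Feature] = []
        for f in features:
            self.add(f)

    def add(self, feature: Feature) -> None:
        self.features.append(feature)
        self._trees.setdefault(feature.chrom, IntervalTree()).addi(
            feature.start, feature.end, feature
        )

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda f: (_RANK[f.cls], f.start),
        )

    @classmethod
    def from_bed(cls, path) -> "FeatureSet":
        """Load BED6 with the feature class in the name column."""
        fs = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                strand = parts[5] if len(parts) > 5 else "+"
                fs.add(Feature(chrom, start, end, strand, name))
        return fs

    def __len__(self) -> int:
        return len(self.features)


def annotate_tag(
    tag: str,
    alignments: Iterable[Alignment],
    features: FeatureSet,
    is_known_mirna: bool,
) -> str:
    """Category of one tag given its alignments and reference-match status.

    Known-miRNA status wins outright (so miRNA reads falling inside genes are
    not lost to the exon class); otherwise the highest-priority feature class
    overlapped by any alignment is used; mapped-but-unmatched tags and
    unmapped tags are ``unannotated``.
    """
    if is_known_mirna:
        return "known_miRNA"
    best = "unannotated"
    for aln in alignments:
        for feat in features.overlapping(aln.chrom, aln.start, aln.start + len(tag)):
            if _RANK[feat.cls] < _RANK[best]:
                best = feat.cls
    return best


def summarize_categories(
    categories: Mapping[str, str], counts: Mapping[str, int]
) -> pd.DataFrame:
    """Per-category totals over reads and over unique tags, with percentages.

    ``categories`` maps tag sequence -> category; ``counts`` maps tag
    sequence -> read count.  Total counts are conserved by construction.
    """
    rows = []
    total_reads = sum(counts[t] for t in categories)
    total_tags = len(categories)
    by_cat_reads: dict[str, int] = {}
    by_cat_tags: dict[str, int] = {}
    for tag, cat in categories.items():
        by_cat_reads[cat] = by_cat_reads.get(cat, 0) + counts[tag]
        by_cat_tags[cat] = by_cat_tags.get(cat, 0) + 1
    for cat in PRIORITY:
        if cat not in by_cat_reads:
            continue
        rows.append(
            {
                "category": cat,
                "total_reads": by_cat_reads[cat],
                "total_pct": 100.0 * by_cat_reads[cat] / total_reads if total_reads else 0.0,
                "unique_tags": by_cat_tags[cat],
                "unique_pct": 100.0 * by_cat_tags[cat] / total_tags if total_tags else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["category", "total_reads", "total_pct", "unique_tags", "unique_pct"])
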