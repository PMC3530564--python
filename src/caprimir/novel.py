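"""Novel miRNA prediction from unannotated, uniquely mapped tags.

Candidate tags must map to exactly one genomic locus, carry at least five
reads, and be unannotated.  For each candidate two genomic windows are
excised (the tag at the 5' end with a 70 nt downstream flank, and the tag at
the 3' end with a 70 nt upstream flank, strand-aware and clipped at
chromosome ends), folded with the single-hairpin MFE model, and judged
against seven stem-loop criteria:

1. number of base pairs in the stem >= 18
2. largest unpaired run on one side within the stem (bulge) <= 18 nt
3. free energy strictly below -20 kcal/mol
4. >= 80% of the mature (tag) bases are base-paired
5. hairpin length (stems + terminal loop, outermost-pair span) >= 53 nt
6. terminal loop length <= 22 nt
7. mature A+U content between 30% and 70% (inclusive)

A candidate whose window passes all seven becomes a predicted novel miRNA;
when both windows pass, the lower-MFE window is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .fold import SecondaryStructure, fold_mfe
from .mapping import Alignment, classify_mapping, reverse_complement

__all__ = [
    "CandidateWindow",
    "HairpinCandidate",
    "HairpinFeatures",
    "CriteriaThresholds",
    "CriteriaVerdict",
    "NovelPrediction",
    "extract_candidates",
    "excise_windows",
    "extract_features",
    "apply_criteria",
    "predict_novel",
    "DEFAULT_MIN_COUNT",
    "DEFAULT_FLANK",
]

DEFAULT_MIN_COUNT = 5
DEFAULT_FLANK = 70
MAX_WINDOW = 150


class CandidateWindow(NamedTuple):
    """One excised genomic window in transcript orientation."""

    sequence: str
    tag_span: tuple[int, int]       # mature (tag) position within the window
    chrom: str
    start: int                      # genomic, 0-based half-open
    end: int
    strand: str


@dataclass(frozen=True)
class HairpinCandidate:
    """A surviving tag with its excised windows."""

    tag: str
    count: int
    alignment: Alignment
    windows: tuple[CandidateWindow, ...]


@dataclass(frozen=True)
class HairpinFeatures:
    """Structural features of a folded candidate used by the criteria."""

    n_stem_pairs: int
    loop_length: Optional[int]       # None when no pair exists
    max_bulge: int
    hairpin_length: int
    mature_in_stem_pct: float
    mature_au_pct: float
    mfe: float


@dataclass(frozen=True)
class CriteriaThresholds:
    """The seven stem-loop gates; defaults are the published values."""

    min_stem_pairs: int = 18
    max_bulge: int = 18
    max_mfe: float = -20.0           # strict: mfe must be < max_mfe
    min_mature_in_stem_pct: float = 80.0
    min_hairpin_length: int = 53
    max_loop_length: int = 22
    mature_au_range: tuple[float, float] = (30.0, 70.0)


class CriteriaVerdict(NamedTuple):
    c1: bool  # stem pairs
    c2: bool  # bulge size
    c3: bool  # free energy
    c4: bool  # mature in stem
    c5: bool  # hairpin length
    c6: bool  # loop length
    c7: bool  # mature A+U content

    @property
    def overall(self) -> bool:
        return all(self)


def excise_windows(
    tag: str,
    alignment: Alignment,
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> tuple[CandidateWindow, ...]:
    """The two candidate windows around one alignment, strand-aware.

    On the minus strand "downstream" runs toward lower genomic coordinates
    and the returned sequence is reverse-complemented into transcript sense.
    Windows are clipped at chromosome ends and deduplicated.
    """
    chrom_seq = genome[alignment.chrom]
    s, e = alignment.start, alignment.start + len(tag)
    if alignment.strand == "+":
        spans = [(s, min(len(chrom_seq), e + flank)), (max(0, s - flank), e)]
    else:
        spans = [(max(0, s - flank), e), (s, min(len(chrom_seq), e + flank))]
    windows = []
    seen = set()
    for gstart, gend in spans:
        if (gstart, gend) in seen:
            continue
        seen.add((gstart, gend))
        seq = chrom_seq[gstart:gend]
        if alignment.strand == "+":
            tag_span = (s - gstart, e - gstart)
        else:
            seq = reverse_complement(seq)
            tag_span = (gend - e, gend - s)
        windows.append(
            CandidateWindow(seq, tag_span, alignment.chrom, gstart, gend, alignment.strand)
        )
    return tuple(windows)


def extract_candidates(
    tag_counts: Mapping[str, int],
    alignments: Mapping[str, Sequence[Alignment]],
    categories: Mapping[str, str],
    genome: Mapping[str, str],
    min_count: int = DEFAULT_MIN_COUNT,
    flank: int = DEFAULT_FLANK,
) -> list[HairpinCandidate]:
    """Filter tags to unique-locus, unannotated, count >= min_count and
    excise their candidate windows."""
    out = []
    for tag in sorted(tag_counts):
        count = tag_counts[tag]
        if count < min_count:
            continue
        if categories.get(tag) != "unannotated":
            continue
        alns = alignments.get(tag, ())
        status, _n = classify_mapping(alns)
        if status != "unique":
            continue
        aln = sorted(alns)[0]
        out.append(
            HairpinCandidate(tag, count, aln, excise_windows(tag, aln, genome, flank))
        )
    return out


def extract_features(
    structure: SecondaryStructure,
    mature_span: tuple[int, int],
    in_stem_mode: str = "paired",
) -> HairpinFeatures:
    """Structural features of a folded window.

    ``in_stem_mode``: 'paired' scores a mature base as in-stem when it is
    base-paired; 'span' scores it in-stem when it lies within the outermost
    pair but outside the terminal loop (so internal bulges count).
    """
    seq = structure.sequence
    m0, m1 = mature_span
    if not (0 <= m0 < m1 <= len(seq)):
        raise ValueError("mature span outside the window")
    mature = seq[m0:m1]
    au = sum(1 for b in mature if b in "AU")
    au_pct = 100.0 * au / len(mature)

    pairs = structure.pairs  # outermost-first
    if not pairs:
        return HairpinFeatures(0, None, 0, 0, 0.0, au_pct, structure.mfe)

    outer = pairs[0]
    inner = pairs[-1]
    loop_length = inner[1] - inner[0] - 1
    max_bulge = 0
    for (i, j), (i2, j2) in zip(pairs, pairs[1:]):
        max_bulge = max(max_bulge, i2 - i - 1, j - j2 - 1)
    hairpin_length = outer[1] - outer[0] + 1

    paired = {p for pair in pairs for p in pair}
    if in_stem_mode == "paired":
        in_stem = sum(1 for p in range(m0, m1) if p in paired)
    elif in_stem_mode == "span":
        loop_range = range(inner[0] + 1, inner[1])
        in_stem = sum(
            1
            for p in range(m0, m1)
            if outer[0] <= p <= outer[1] and p not in loop_range
        )
    else:
        raise ValueError(f"unknown in_stem_mode {in_stem_mode!r}")
    in_stem_pct = 100.0 * in_stem / len(mature)
    return HairpinFeatures(
        n_stem_pairs=len(pairs),
        loop_length=loop_length,
        max_bulge=max_bulge,
        hairpin_length=hairpin_length,
        mature_in_stem_pct=in_stem_pct,
        mature_au_pct=au_pct,
        mfe=structure.mfe,
    )


def apply_criteria(
    features: HairpinFeatures, thresholds: CriteriaThresholds = CriteriaThresholds()
) -> CriteriaVerdict:
    """Evaluate the seven stem-loop criteria on extracted features."""
    t = thresholds
    lo_au, hi_au = t.mature_au_range
    return CriteriaVerdict(
        c1=features.n_stem_pairs >= t.min_stem_pairs,
        c2=features.max_bulge <= t.max_bulge,
        c3=features.mfe < t.max_mfe,
        c4=features.mature_in_stem_pct >= t.min_mature_in_stem_pct,
        c5=features.hairpin_length >= t.min_hairpin_length,
        c6=features.loop_length is not None and features.loop_length <= t.max_loop_length,
        c7=lo_au <= features.mature_au_pct <= hi_au,
    )


@dataclass(frozen=True)
class NovelPrediction:
    """One predicted novel miRNA (the winning window of one candidate)."""

    novel_id: str
    tag: str
    window: CandidateWindow
    structure: SecondaryStructure
    features: HairpinFeatures
    verdict: CriteriaVerdict
    count_d: int
    count_p: int

    @property
    def total_count(self) -> int:
        return self.count_d + self.count_p


def predict_novel(
    candidates: Iterable[HairpinCandidate],
    counts_d: Mapping[str, int],
    counts_p: Mapping[str, int],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    in_stem_mode: str = "paired",
) -> list[NovelPrediction]:
    """Fold candidate windows, apply the criteria and name the survivors.

    Of a candidate's two windows the passing one with lower MFE wins;
    duplicate windows (same genomic span and strand) are merged.  Survivors
    are named novel_miR_1..n in descending total read count.
    """
    winners = []
    seen_windows: set[tuple[str, int, int, str]] = set()
    for cand in candidates:
        best: Optional[tuple[float, CandidateWindow, SecondaryStructure, HairpinFeatures, CriteriaVerdict]] = None
        for window in cand.windows:
            key = (window.chrom, window.start, window.end, window.strand)
            if key in seen_windows:
                continue
            structure = fold_mfe(window.sequence)
            features = extract_features(structure, window.tag_span, in_stem_mode)
            verdict = apply_criteria(features, thresholds)
            if not verdict.overall:
                continue
            if best is None or structure.mfe < best[0]:
                best = (structure.mfe, window, structure, features, verdict)
        if best is None:
            continue
        _, window, structure, features, verdict = best
        seen_windows.add((window.chrom, window.start, window.end, window.strand))
        winners.append(
            NovelPrediction(
                novel_id="",
                tag=cand.tag,
                window=window,
                structure=structure,
                features=features,
                verdict=verdict,
                count_d=int(counts_d.get(cand.tag, 0)),
                count_p=int(counts_p.get(cand.tag, 0)),
            )
        )
    winners.sort(key=lambda w: (-w.total_count, w.tag))
    return [replace(w, novel_id=f"novel_miR_{i}") for i, w in enumerate(winners, start=1)]


def predictions_frame(predictions: Iterable[NovelPrediction]) -> pd.DataFrame:
    rows = []
    for p in predictions:
        rows.append(
            {
                "id": p.novel_id,
                "chrom": p.window.chrom,
                "start": p.window.start,
                "end": p.window.end,
                "strand": p.window.strand,
                "mature": p.tag,
                "precursor": p.window.sequence,
                "structure": p.structure.dot_bracket,
                "mfe": round(p.structure.mfe, 2),
                "stem_pairs": p.features.n_stem_pairs,
                "loop": p.features.loop_length,
                "D": p.count_d,
                "P": p.count_p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "start", "end", "strand", "mature", "precursor",
                 "structure", "mfe", "stem_pairs", "loop", "D", "P"],
    )
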