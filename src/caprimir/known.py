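"""Conserved miRNA identification against a mature/precursor reference.

Tags are matched to reference entries in the miRBase flavour (a mature FASTA
plus a hairpin FASTA).  A tag matches a mature miRNA when it aligns inside
the precursor with at most ``max_mismatch`` substitutions and both of its
ends fall within ``max_shift`` nt of the recorded mature ends, which admits
the common templated isomiR trimming/extension variants while rejecting loop
or star-arm fragments.  Arm categories (miRNA / miRNA* / -5p / -3p) are taken
from the reference naming convention.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "MiRBaseEntry",
    "Mature",
    "Match",
    "load_mirbase",
    "match_conserved",
    "ConservedMatcher",
    "assign_arm",
    "count_table",
]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


class Mature(NamedTuple):
    label: str       # full mature name, e.g. "cap-miR-5-3p", "cap-miR-2*"
    sequence: str    # stored in DNA alphabet (T)
    offset: int      # start within the precursor


@dataclass(frozen=True)
class MiRBaseEntry:
    """A precursor and its annotated mature sequences.

    Every mature sequence is a substring of the precursor at its recorded
    offset (checked at load time).
    """

    name: str
    precursor_seq: str
    matures: tuple[Mature, ...]

    def __post_init__(self) -> None:
        for m in self.matures:
            if self.precursor_seq[m.offset : m.offset + len(m.sequence)] != m.sequence:
                raise ValueError(
                    f"mature {m.label} is not at offset {m.offset} of precursor {self.name}"
                )


class Match(NamedTuple):
    entry: MiRBaseEntry
    mature: Mature
    start: int        # tag start within the precursor
    mismatches: int
    shift: int        # |start shift| + |end shift| relative to the mature

    @property
    def arm(self) -> str:
        return assign_arm(self.mature.label)


def _stem_name(mature_label: str) -> str:
    """Reduce a mature name to its precursor stem name for linking."""
    name = mature_label
    if name.endswith("*"):
        name = name[:-1]
    for suffix in ("-5p", "-3p"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name.lower()


def load_mirbase(mature_fa, hairpin_fa) -> list[MiRBaseEntry]:
    """Build entries from miRBase-flavour mature and hairpin FASTA files.

    Headers are ``>name accession``; U and T are both accepted.  Matures are
    linked to the precursor whose stem name matches (case-insensitive,
    ignoring -5p/-3p/* decorations) and located by exact substring search.
    """
    from .io import read_fasta

    hairpins = {name.split()[0]: _normalize(seq) for name, seq in read_fasta(hairpin_fa)}
    by_stem = { _stem_name(n): (n, s) for n, s in hairpins.items() }
    matures_by_prec: dict[str, list[Mature]] = defaultdict(list)
    for name, seq in read_fasta(mature_fa):
        label = name.split()[0]
        seq = _normalize(seq)
        stem = _stem_name(label)
        target = by_stem.get(stem)
        if target is None:
            # fall back to substring search over all precursors
            target = next(((n, s) for n, s in hairpins.items() if seq in s), None)
            if target is None:
                raise ValueError(f"no precursor found for mature {label}")
        prec_name, prec_seq = target
        offset = prec_seq.find(seq)
        if offset == -1:
            raise ValueError(f"mature {label} not a substring of precursor {prec_name}")
        matures_by_prec[prec_name].append(Mature(label, seq, offset))
    entries = [
        MiRBaseEntry(name, hairpins[name], tuple(sorted(ms, key=lambda m: m.offset)))
        for name, ms in matures_by_prec.items()
    ]
    entries.sort(key=lambda e: e.name)
    return entries


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match_key(m: Match) -> tuple:
    return (m.mismatches, m.shift, m.entry.name, m.mature.label, m.start)


def match_conserved(
    tag: str,
    entries: Sequence[MiRBaseEntry],
    max_mismatch: int = 0,
    max_shift: int = 2,
) -> Optional[Match]:
    """Best reference match for ``tag``, or None.

    Ties are broken by (fewer mismatches, smaller total end shift,
    lexicographic entry then mature name), so a tag matching several families
    is counted exactly once.
    """
    tag = _normalize(tag)
    best: Optional[Match] = None
    for entry in entries:
        prec = entry.precursor_seq
        for mature in entry.matures:
            m_end = mature.offset + len(mature.sequence)
            for start in range(
                max(0, mature.offset - max_shift), mature.offset + max_shift + 1
            ):
                end = start + len(tag)
                if end > len(prec) or abs(end - m_end) > max_shift:
                    continue
                mm = _hamming(tag, prec[start:end])
                if mm > max_mismatch:
                    continue
                cand = Match(entry, mature, start, mm, abs(start - mature.offset) + abs(end - m_end))
                if best is None or _match_key(cand) < _match_key(best):
                    best = cand
    return best


class ConservedMatcher:
    """Reference matcher with a precomputed exact-substring fast path.

    With ``max_mismatch == 0`` (the default), every admissible precursor
    substring (all start/end shifts within ``max_shift``) is enumerated once
    into a dictionary, making per-tag matching O(1).  Semantics, including
    tie-breaks, are identical to :func:`match_conserved`; with mismatches
    allowed it falls back to the scanning implementation.
    """

    def __init__(self, entries: Sequence[MiRBaseEntry], max_mismatch: int = 0, max_shift: int = 2):
        self.entries = list(entries)
        self.max_mismatch = max_mismatch
        self.max_shift = max_shift
        self._exact: dict[str, Match] | None = None
        if max_mismatch == 0:
            lookup: dict[str, Match] = {}
            for entry in self.entries:
                prec = entry.precursor_seq
                for mature in entry.matures:
                    m_end = mature.offset + len(mature.sequence)
                    for start in range(
                        max(0, mature.offset - max_shift), mature.offset + max_shift + 1
                    ):
                        for end in range(
                            max(start + 1, m_end - max_shift),
                            min(len(prec), m_end + max_shift) + 1,
                        ):
                            sub = prec[start:end]
                            cand = Match(
                                entry, mature, start, 0,
                                abs(start - mature.offset) + abs(end - m_end),
                            )
                            prev = lookup.get(sub)
                            if prev is None or _match_key(cand) < _match_key(prev):
                                lookup[sub] = cand
            self._exact = lookup

    def match(self, tag: str) -> Optional[Match]:
        if self._exact is not None:
            return self._exact.get(_normalize(tag))
        return match_conserved(tag, self.entries, self.max_mismatch, self.max_shift)


def assign_arm(mature_label: str) -> str:
    """Arm category from the reference naming convention."""
    if mature_label.endswith("*"):
        return "miRNA*"
    if mature_label.endswith("-5p"):
        return "miRNA-5p"
    if mature_label.endswith("-3p"):
        return "miRNA-3p"
    return "miRNA"


def count_table(
    assignments: Mapping[str, tuple[int, Match]],
) -> tuple[pd.DataFrame, dict]:
    """Per-miRNA counts plus a library summary.

    ``assignments`` maps tag sequence -> (read count, Match).  The table has
    one row per matched mature miRNA, sorted by total reads descending; the
    summary tallies detected miRNAs, precursors hit, unique tags matched and
    total reads matched, plus detected miRNAs per arm category.
    """
    per_mirna: dict[str, dict] = {}
    precursors: set[str] = set()
    total_reads = 0
    for _tag, (count, match) in assignments.items():
        label = match.mature.label
        rec = per_mirna.setdefault(
            label,
            {"mirna": label, "precursor": match.entry.name, "arm": match.arm,
             "unique_tags": 0, "total_reads": 0},
        )
        rec["unique_tags"] += 1
        rec["total_reads"] += count
        precursors.add(match.entry.name)
        total_reads += count
    table = pd.DataFrame(
        sorted(per_mirna.values(), key=lambda r: (-r["total_reads"], r["mirna"])),
        columns=["mirna", "precursor", "arm", "unique_tags", "total_reads"],
    )
    arm_counts = {arm: 0 for arm in ("miRNA", "miRNA*", "miRNA-5p", "miRNA-3p")}
    for rec in per_mirna.values():
        arm_counts[rec["arm"]] += 1
    summary = {
        "detected_mirnas": len(per_mirna),
        "precursors_hit": len(precursors),
        "unique_tags_matched": len(assignments),
        "total_reads_matched": total_reads,
        "arm_counts": arm_counts,
    }
    return table, summary
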