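"""Synthetic two-library small-RNA dataset with exact ground truth.

The generator builds a toy genome with planted loci — known miRNA hairpins,
novel hairpins that satisfy all seven stem-loop criteria, decoy hairpins that
violate at least one named criterion, and non-miRNA loci (rRNA, tRNA, snRNA,
snoRNA, scRNA, srpRNA, repeat, exon, intron) — then simulates a dry-period
(D) and a peak-lactation (P) read library over it, with adapter artifacts at
configured fractions, star-strand reads at a configured fraction of mature
reads, and log2 fold changes planted between the two conditions.

Ground truth is exact by construction:

* hairpin and decoy loci are *constructed*, not sampled, and every novel
  hairpin is verified through the actual candidate-window fold/criteria
  checker (at least one excision window passes); every decoy is verified to
  fail in both windows, with its recorded violated criterion false in both;
* every emitted insert is rejection-sampled against the read classifier's
  rules, so each read classifies exactly as its intended category and the
  per-category manifest counts match the QC report to the read;
* artifact-class counts are drawn multinomially over the library total
  (a joint Poisson conditioned on the total), planted-locus counts are
  Poisson around their condition means, and the unannotated-background class
  absorbs the remainder, so category counts sum to ``reads_per_library``
  exactly.

The same seed always reproduces byte-identical genomes, reads and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .annotation import NCRNA_CLASSES
from .fold import fold_mfe
from .mapping import reverse_complement
from .novel import (
    CriteriaThresholds,
    CriteriaVerdict,
    apply_criteria,
    extract_features,
)
from .preprocess import starts_with_adapter5_suffix

__all__ = [
    "SimulationConfig",
    "PlantedLocus",
    "GroundTruthManifest",
    "SimRead",
    "LibraryTruth",
    "SimulatedDataset",
    "construct_passing_hairpin",
    "build_toy_genome",
    "simulate_library",
    "simulate_dataset",
]

CHROM = "chr1"
FLANK = 70  # matches the candidate-excision flank of the prediction module

FEATURE_LOCUS_CLASSES = (*NCRNA_CLASSES, "repeat", "exon", "intron")
HAIRPIN_CLASSES = ("known_mirna", "novel_hairpin", "decoy_hairpin")

ARTIFACT_KEYS = (
    "low_quality",
    "adapter3_null",
    "insert_null",
    "adapter5_contaminant",
    "polyA",
    "too_short",
)

#: insert length distribution of background reads, mode 22 nt
BACKGROUND_LENGTH_PROBS = {
    18: 0.02, 19: 0.05, 20: 0.08, 21: 0.14, 22: 0.30, 23: 0.14, 24: 0.08,
    25: 0.05, 26: 0.04, 27: 0.03, 28: 0.03, 29: 0.02, 30: 0.02,
}

#: mature length distribution of planted hairpins, mode 22 nt
MATURE_LENGTH_PROBS = {20: 0.10, 21: 0.20, 22: 0.45, 23: 0.15, 24: 0.10}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the shape of a deep-sequenced mammary-gland small-RNA
    library pair at desk scale: two libraries of 2e5 reads, ~95% clean,
    insert length mode 22 nt, a known-miRNA-dominated clean fraction, and
    six known miRNAs with planted |log2 fold change| = 2.
    """

    seed: int = 1
    genome_length: int = 100_000
    n_known_mirnas: int = 30
    n_novel_hairpins: int = 10
    n_decoy_hairpins: int = 10
    n_ncrna_loci: int = 2            # loci per feature class
    reads_per_library: int = 200_000
    read_length: int = 36
    adapter_3p: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter_5p: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    # artifact fractions of raw reads
    frac_low_quality: float = 0.005
    frac_no_adapter: float = 0.002
    frac_insert_null: float = 0.001
    frac_5p_contaminant: float = 0.005
    frac_polyA: float = 0.0005
    frac_short: float = 0.040
    # composition of the clean fraction
    frac_known: float = 0.45
    frac_novel: float = 0.05
    frac_decoy: float = 0.05
    frac_ncrna: float = 0.135
    star_fraction: float = 0.05
    planted_log2fc: Optional[list[tuple[str, float]]] = None  # None = defaults
    abundance_sigma: float = 0.7     # lognormal spread of per-locus abundance

    def artifact_fractions(self) -> dict[str, float]:
        return {
            "low_quality": self.frac_low_quality,
            "adapter3_null": self.frac_no_adapter,
            "insert_null": self.frac_insert_null,
            "adapter5_contaminant": self.frac_5p_contaminant,
            "polyA": self.frac_polyA,
            "too_short": self.frac_short,
        }

    def validate(self) -> None:
        fracs = list(self.artifact_fractions().values()) + [
            self.frac_known, self.frac_novel, self.frac_decoy, self.frac_ncrna,
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(self.artifact_fractions().values()) >= 1.0:
            raise ValueError("artifact fractions must sum to < 1")
        if not 0.0 < self.star_fraction < 1.0:
            raise ValueError("star_fraction must lie in (0, 1)")
        if self.frac_known + self.frac_novel + self.frac_decoy + self.frac_ncrna > 1.0:
            raise ValueError("clean-class fractions must sum to <= 1")
        if self.reads_per_library <= 0 or self.genome_length <= 0:
            raise ValueError("sizes must be positive")
        if self.read_length < 24:
            raise ValueError("read_length too short for insert+adapter evidence")

    def default_log2fc(self) -> list[tuple[str, float]]:
        """Six known miRNAs with planted +/-2 log2 fold change (P vs D)."""
        ups = [(f"cap-mir-{i}", 2.0) for i in (1, 2, 3)]
        downs = [(f"cap-mir-{i}", -2.0) for i in (4, 5, 6)]
        return ups + downs


@dataclass
class PlantedLocus:
    """One planted genomic locus with its ground truth."""

    id: str
    cls: str                         # known_mirna / novel_hairpin / ... / intron
    chrom: str
    start: int                       # core locus span, 0-based half-open
    end: int
    strand: str
    base_mean: float = 0.0           # expected mature reads per library (D)
    log2fc: float = 0.0              # planted P-vs-D fold change
    mature_seq: str = ""             # hairpin classes only (DNA alphabet)
    star_seq: str = ""
    mature_name: str = ""
    star_name: str = ""
    mature_start: int = -1           # genomic span of the mature read
    mature_end: int = -1
    precursor_seq: str = ""          # transcript-sense hairpin sequence
    expected_verdict: Optional[CriteriaVerdict] = None
    violated: Optional[str] = None   # decoys: criterion false in both windows


@dataclass
class GroundTruthManifest:
    """Everything the downstream tests need to score recovery exactly."""

    loci: list[PlantedLocus]
    chrom: str = CHROM
    genome_length: int = 0
    background_intervals: list[tuple[int, int]] = field(default_factory=list)
    library_totals: dict[str, int] = field(default_factory=dict)
    true_category_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    locus_counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)

    def by_class(self, cls: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.cls == cls]

    def locus(self, locus_id: str) -> PlantedLocus:
        for l in self.loci:
            if l.id == locus_id:
                return l
        raise KeyError(locus_id)


class SimRead(NamedTuple):
    id: str
    sequence: str
    quality: str


@dataclass
class LibraryTruth:
    """Intended per-category and per-locus read counts for one library."""

    condition: str
    total: int
    category_counts: dict[str, int]
    locus_counts: dict[str, dict[str, int]]  # locus id -> {"mature": n, "star": n}


# ---------------------------------------------------------------------------
# sequence construction helpers

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rand_seq(rng: np.random.Generator, n: int, probs: Optional[Sequence[float]] = None) -> str:
    return b"".join(rng.choice(_BASES, size=n, p=probs)).decode()


def _insert_ok(insert: str, adapter_3p: str, adapter_5p: str) -> bool:
    """True when the insert will classify as clean with itself as the tag."""
    if "N" in insert:
        return False
    if adapter_3p and adapter_3p[:6] in insert:
        return False
    if adapter_5p and starts_with_adapter5_suffix(insert, adapter_5p):
        return False
    if insert.count("A") / len(insert) >= 0.8:
        return False
    return True


def _sample_mature(
    rng: np.random.Generator,
    length: int,
    adapter_3p: str,
    adapter_5p: str,
    au_range: tuple[float, float] = (0.35, 0.65),
    probs: Optional[Sequence[float]] = None,
    max_tries: int = 200,
) -> str:
    """A mature sequence whose A+T fraction lies in ``au_range`` and whose
    read (and its star) will survive cleaning untouched."""
    for _ in range(max_tries):
        seq = _rand_seq(rng, length, probs)
        au = (seq.count("A") + seq.count("T")) / length
        if not au_range[0] <= au <= au_range[1]:
            continue
        if _insert_ok(seq, adapter_3p, adapter_5p) and _insert_ok(
            reverse_complement(seq), adapter_3p, adapter_5p
        ):
            return seq
    raise RuntimeError("could not sample an admissible mature sequence")


#: substitutions that cannot pair with the keyed base (DNA alphabet, G-T
#: wobble counted as pairing)
_NONPAIRING = {"A": "ACG", "C": "ACT", "G": "AG", "T": "CT"}


def _mutate_star_arm(
    seq: str,
    m0: int,
    m1: int,
    rng: np.random.Generator,
    n_mut: int = 3,
    min_gap: int = 3,
) -> str:
    """Break ``n_mut`` mature-side pairs by mutating the star-side partner.

    The construction is a perfect inverted repeat, so position ``t`` pairs
    with ``len(seq) - 1 - t``; substituting a non-pairing base there leaves
    the mature sequence untouched while making the mature/star duplex
    imperfect.  Without this, every mature tag would also match the star arm
    of its own hairpin on the opposite strand exactly and be discarded as a
    multi-mapper — real precursor duplexes always carry mismatches.
    """
    n = len(seq)
    lo, hi = m0 + 2, m1 - 2
    for _ in range(100):
        ts = sorted(int(t) for t in rng.choice(np.arange(lo, hi), size=n_mut, replace=False))
        if all(b - a >= min_gap for a, b in zip(ts, ts[1:])):
            break
    else:
        raise RuntimeError("could not place star-arm mutations")
    out = list(seq)
    for t in ts:
        partner = n - 1 - t
        choices = [c for c in _NONPAIRING[seq[t]] if c != seq[partner]]
        out[partner] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def construct_passing_hairpin(
    rng: np.random.Generator,
    mature_length: int,
    adapter_3p: str = "",
    adapter_5p: str = "",
    max_tries: int = 50,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Build a hairpin whose fold passes all seven criteria.

    Layout: 5 nt extension + mature + 8 nt loop + reverse complement of the
    5' arm, with three star-side pairs broken (see :func:`_mutate_star_arm`)
    so the mature/star duplex is imperfect as in real precursors.  The stem
    keeps ``mature_length + 2`` pairs and >= 85% of mature bases paired; the
    construction is verified by folding and applying the criteria, retrying
    on the rare failure.

    Returns (sequence, mature span, star span), spans 0-based half-open.
    """
    if not 20 <= mature_length <= 24:
        raise ValueError("mature_length must be in [20, 24]")
    ext = 5
    for _ in range(max_tries):
        mature = _sample_mature(rng, mature_length, adapter_3p, adapter_5p)
        arm5 = _rand_seq(rng, ext) + mature
        loop = _rand_seq(rng, 8)
        seq = arm5 + loop + reverse_complement(arm5)
        m_span = (ext, ext + mature_length)
        seq = _mutate_star_arm(seq, *m_span, rng)
        s_start = len(arm5) + len(loop)
        s_span = (s_start, s_start + mature_length)
        star = seq[s_span[0] : s_span[1]]
        if not (_insert_ok(star, adapter_3p, adapter_5p) if adapter_3p else True):
            continue
        structure = fold_mfe(seq)
        verdict = apply_criteria(extract_features(structure, m_span))
        if verdict.overall:
            return seq, m_span, s_span
    raise RuntimeError("failed to construct a passing hairpin")


def _windows_of(segment: str, m0: int, m1: int) -> list[tuple[str, tuple[int, int]]]:
    """The two candidate windows the prediction stage would excise for a tag
    at segment positions [m0, m1), given >= FLANK nt of context each side."""
    w1 = segment[m0 : m1 + FLANK]
    w2 = segment[m0 - FLANK : m1]
    return [(w1, (0, m1 - m0)), (w2, (FLANK, FLANK + (m1 - m0)))]


def _window_verdicts(
    segment: str, m0: int, m1: int
) -> list[tuple[CriteriaVerdict, float]]:
    out = []
    for wseq, span in _windows_of(segment, m0, m1):
        structure = fold_mfe(wseq)
        verdict = apply_criteria(extract_features(structure, span))
        out.append((verdict, structure.mfe))
    return out


def _build_decoy_core(
    rng: np.random.Generator, kind: str, adapter_3p: str, adapter_5p: str
) -> tuple[str, tuple[int, int], tuple[int, int], str]:
    """Decoy hairpin core violating one designed criterion.

    Kinds: 'high_au' (c7: mature A+U ~80%), 'big_loop' (c6: 30 nt terminal
    loop), 'loop_mature' (c4: mature spans the loop), 'random_weak'
    (c1/c3: no real stem at all).
    """
    if kind == "high_au":
        mature = _sample_mature(
            rng, 22, adapter_3p, adapter_5p,
            au_range=(0.75, 0.90), probs=[0.40, 0.10, 0.10, 0.40],
        )
        arm5 = _rand_seq(rng, 5) + mature
        seq = _mutate_star_arm(arm5 + _rand_seq(rng, 8) + reverse_complement(arm5), 5, 27, rng)
        return seq, (5, 27), (len(arm5) + 8, len(arm5) + 8 + 22), "c7"
    if kind == "big_loop":
        mature = _sample_mature(rng, 22, adapter_3p, adapter_5p)
        arm5 = _rand_seq(rng, 5) + mature
        seq = _mutate_star_arm(arm5 + "A" * 30 + reverse_complement(arm5), 5, 27, rng)
        return seq, (5, 27), (len(arm5) + 30, len(arm5) + 30 + 22), "c6"
    if kind == "loop_mature":
        for _ in range(200):
            stem = _rand_seq(rng, 26)
            loop = _rand_seq(rng, 8)
            # a near-palindromic loop would let the mature tag map back onto
            # the minus strand of its own locus; keep the loop asymmetric
            if sum(a != b for a, b in zip(loop, reverse_complement(loop))) < 2:
                continue
            seq = stem + loop + reverse_complement(stem)
            mature = seq[16:38]  # last 10 of the 5' arm + loop + 4 of the 3' arm
            au = (mature.count("A") + mature.count("T")) / len(mature)
            if 0.35 <= au <= 0.65 and _insert_ok(mature, adapter_3p, adapter_5p):
                return seq, (16, 38), (-1, -1), "c4"
        raise RuntimeError("failed to build loop-spanning decoy")
    if kind == "random_weak":
        for _ in range(200):
            mature = _sample_mature(rng, 22, adapter_3p, adapter_5p)
            seq = _rand_seq(rng, 34) + mature + _rand_seq(rng, 34)
            return seq, (34, 56), (-1, -1), "c3"
        raise RuntimeError("failed to build weak decoy")
    raise ValueError(f"unknown decoy kind {kind!r}")


DECOY_KINDS = ("high_au", "big_loop", "loop_mature", "random_weak")


# ---------------------------------------------------------------------------
# genome construction


def build_toy_genome(config: SimulationConfig) -> tuple[dict[str, str], GroundTruthManifest]:
    """Plant all loci into a toy genome and record exact ground truth.

    Hairpin-class loci are embedded with 70 nt dedicated flanks; novel
    hairpins are accepted only if at least one of their two candidate
    excision windows passes all seven criteria, decoys only if both windows
    fail and the designed criterion is false in both.  Loci are placed at
    non-overlapping positions separated by random background gaps; remaining
    space is uniform random background.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a3, a5 = config.adapter_3p, config.adapter_5p

    # conservative capacity pre-check before any expensive construction
    n_hairpins = config.n_known_mirnas + config.n_novel_hairpins + config.n_decoy_hairpins
    n_feat = config.n_ncrna_loci * len(FEATURE_LOCUS_CLASSES)
    min_needed = n_hairpins * (58 + 2 * FLANK) + n_feat * 90 + (n_hairpins + n_feat + 1) * 80
    if min_needed > config.genome_length:
        raise ValueError("planted loci exceed genome capacity")

    mature_lengths = list(MATURE_LENGTH_PROBS)
    mature_probs = np.array([MATURE_LENGTH_PROBS[k] for k in mature_lengths])

    segments: list[tuple[PlantedLocus, str, int, int, int, int]] = []
    # (locus, segment_seq, core_off, core_len, mature_off, mature_len)

    def _hairpin_names(i: int) -> tuple[str, str, str]:
        if i % 2 == 0:
            return f"cap-mir-{i}", f"cap-miR-{i}", f"cap-miR-{i}*"
        return f"cap-mir-{i}", f"cap-miR-{i}-5p", f"cap-miR-{i}-3p"

    # known miRNA hairpins
    for i in range(1, config.n_known_mirnas + 1):
        L = int(rng.choice(mature_lengths, p=mature_probs))
        seq, m_span, s_span = construct_passing_hairpin(rng, L, a3, a5)
        prec_name, mat_name, star_name = _hairpin_names(i)
        locus = PlantedLocus(
            id=prec_name, cls="known_mirna", chrom=CHROM, start=-1, end=-1,
            strand="+", mature_seq=seq[m_span[0]:m_span[1]],
            star_seq=seq[s_span[0]:s_span[1]],
            mature_name=mat_name, star_name=star_name, precursor_seq=seq,
        )
        segment = _rand_seq(rng, FLANK) + seq + _rand_seq(rng, FLANK)
        segments.append((locus, segment, FLANK, len(seq), FLANK + m_span[0], m_span[1] - m_span[0]))

    # novel hairpins: validated through the candidate-window checker
    for i in range(1, config.n_novel_hairpins + 1):
        for _try in range(60):
            L = int(rng.choice(mature_lengths, p=mature_probs))
            seq, m_span, s_span = construct_passing_hairpin(rng, L, a3, a5)
            segment = _rand_seq(rng, FLANK) + seq + _rand_seq(rng, FLANK)
            m0, m1 = FLANK + m_span[0], FLANK + m_span[1]
            verdicts = _window_verdicts(segment, m0, m1)
            passing = [v for v, _mfe in verdicts if v.overall]
            if passing:
                break
        else:
            raise RuntimeError("failed to plant a passing novel hairpin")
        locus = PlantedLocus(
            id=f"novel-hp-{i}", cls="novel_hairpin", chrom=CHROM, start=-1, end=-1,
            strand="+", mature_seq=seq[m_span[0]:m_span[1]],
            star_seq=seq[s_span[0]:s_span[1]], precursor_seq=seq,
            expected_verdict=passing[0],
        )
        segments.append((locus, segment, FLANK, len(seq), m0, m_span[1] - m_span[0]))

    # decoy hairpins: must fail overall in both windows, and violate the
    # designed criterion in the window that actually contains the hairpin
    # (the tag-at-5'-end window; the other window lacks the 3' arm entirely)
    for i in range(1, config.n_decoy_hairpins + 1):
        kind = DECOY_KINDS[(i - 1) % len(DECOY_KINDS)]
        for _try in range(60):
            core, m_span, s_span, designed = _build_decoy_core(rng, kind, a3, a5)
            if s_span[0] >= 0 and not _insert_ok(core[s_span[0]:s_span[1]], a3, a5):
                continue
            segment = _rand_seq(rng, FLANK) + core + _rand_seq(rng, FLANK)
            m0, m1 = FLANK + m_span[0], FLANK + m_span[1]
            verdicts = _window_verdicts(segment, m0, m1)
            if any(v.overall for v, _mfe in verdicts):
                continue
            if kind == "random_weak":
                # name the first criterion false in both windows
                for c in ("c3", "c1", "c2", "c4"):
                    idx = int(c[1]) - 1
                    if all(not v[idx] for v, _mfe in verdicts):
                        designed = c
                        break
                else:
                    continue
            if not verdicts[0][0][int(designed[1]) - 1]:
                break
        else:
            raise RuntimeError(f"failed to plant decoy of kind {kind}")
        star = core[s_span[0]:s_span[1]] if s_span[0] >= 0 else ""
        locus = PlantedLocus(
            id=f"decoy-hp-{i}", cls="decoy_hairpin", chrom=CHROM, start=-1, end=-1,
            strand="+", mature_seq=core[m_span[0]:m_span[1]], star_seq=star,
            precursor_seq=core, expected_verdict=verdicts[0][0], violated=designed,
        )
        segments.append((locus, segment, FLANK, len(core), m0, m_span[1] - m_span[0]))

    # non-miRNA feature loci
    for cls in FEATURE_LOCUS_CLASSES:
        for i in range(1, config.n_ncrna_loci + 1):
            length = int(rng.integers(90, 181))
            seq = _rand_seq(rng, length)
            locus = PlantedLocus(
                id=f"{cls}-{i}", cls=cls, chrom=CHROM, start=-1, end=-1,
                strand="+", precursor_seq=seq,
            )
            segments.append((locus, seq, 0, length, -1, 0))

    # assembly with random gaps; check capacity
    order = rng.permutation(len(segments))
    min_gap, max_gap = 80, 200
    total_seg = sum(len(s[1]) for s in segments)
    if total_seg + (len(segments) + 1) * min_gap > config.genome_length:
        raise ValueError("planted loci exceed genome capacity")

    parts: list[str] = []
    background: list[tuple[int, int]] = []
    pos = 0
    loci: list[PlantedLocus] = []
    for idx in order:
        locus, segment, core_off, core_len, mat_off, mat_len = segments[idx]
        gap = int(rng.integers(min_gap, max_gap + 1))
        gap_seq = _rand_seq(rng, gap)
        parts.append(gap_seq)
        background.append((pos, pos + gap))
        pos += gap
        strand = "+" if rng.random() < 0.5 else "-"
        seg_seq = segment if strand == "+" else reverse_complement(segment)
        seg_start = pos
        parts.append(seg_seq)
        pos += len(segment)
        if strand == "+":
            start = seg_start + core_off
            end = start + core_len
            m_start = seg_start + mat_off
        else:
            end = seg_start + len(segment) - core_off
            start = end - core_len
            m_start = seg_start + len(segment) - mat_off - mat_len
        locus.strand = strand
        locus.start, locus.end = start, end
        if mat_len:
            locus.mature_start, locus.mature_end = m_start, m_start + mat_len
        loci.append(locus)
    if pos > config.genome_length:
        raise ValueError("planted loci exceed genome capacity")
    pad = config.genome_length - pos
    if pad:
        parts.append(_rand_seq(rng, pad))
        background.append((pos, pos + pad))
    genome_seq = "".join(parts)
    assert len(genome_seq) == config.genome_length

    # per-locus base abundances (expected mature reads in the D library)
    clean_expected = config.reads_per_library * (1.0 - sum(config.artifact_fractions().values()))
    fc_map = dict(config.planted_log2fc if config.planted_log2fc is not None
                  else config.default_log2fc())
    for cls, frac in (
        ("known_mirna", config.frac_known),
        ("novel_hairpin", config.frac_novel),
        ("decoy_hairpin", config.frac_decoy),
    ):
        group = [l for l in loci if l.cls == cls]
        if not group:
            continue
        weights = rng.lognormal(0.0, config.abundance_sigma, size=len(group))
        weights /= weights.sum()
        for locus, w in zip(group, weights):
            locus.base_mean = frac * clean_expected * float(w)
            locus.log2fc = float(fc_map.get(locus.id, 0.0))
    feature_group = [l for l in loci if l.cls in FEATURE_LOCUS_CLASSES]
    if feature_group:
        per = config.frac_ncrna * clean_expected / len(feature_group)
        for locus in feature_group:
            locus.base_mean = per

    manifest = GroundTruthManifest(
        loci=loci,
        genome_length=config.genome_length,
        background_intervals=background,
    )
    return {CHROM: genome_seq}, manifest


# ---------------------------------------------------------------------------
# read simulation


def _transcript_slice(genome: Mapping[str, str], locus: PlantedLocus, off: int, length: int) -> str:
    """Sub-fragment of a planted locus in transcript orientation."""
    seq = genome[locus.chrom][locus.start : locus.end]
    if locus.strand == "-":
        seq = reverse_complement(seq)
    return seq[off : off + length]


def simulate_library(
    genome: Mapping[str, str],
    manifest: GroundTruthManifest,
    config: SimulationConfig,
    condition: str,
) -> tuple[list[SimRead], LibraryTruth]:
    """Simulate one condition's FASTQ-ready reads plus its true counts.

    ``condition`` is 'D' (dry period) or 'P' (peak lactation); planted log2
    fold changes scale the P-condition means by 2**fc.
    """
    if condition not in ("D", "P"):
        raise ValueError("condition must be 'D' or 'P'")
    config.validate()
    cond_idx = 0 if condition == "D" else 1
    rng = np.random.default_rng([config.seed, 1000 + cond_idx])
    a3, a5 = config.adapter_3p, config.adapter_5p
    total = config.reads_per_library
    read_len = config.read_length

    art_fracs = config.artifact_fractions()
    probs = list(art_fracs.values())
    probs.append(1.0 - sum(probs))
    counts_vec = rng.multinomial(total, probs)
    category_counts = dict(zip(ARTIFACT_KEYS, map(int, counts_vec[:-1])))
    n_clean = int(counts_vec[-1])

    locus_counts: dict[str, dict[str, int]] = {}
    clean_class_counts: dict[str, int] = {}
    inserts: list[tuple[str, str]] = []  # (category, insert)

    bg_lengths = list(BACKGROUND_LENGTH_PROBS)
    bg_probs = np.array([BACKGROUND_LENGTH_PROBS[k] for k in bg_lengths])

    # planted loci; fold changes split symmetrically across conditions so
    # the planted totals stay near the configured class fractions
    for locus in manifest.loci:
        if locus.base_mean <= 0:
            continue
        half = locus.log2fc / 2.0
        mean = locus.base_mean * (2.0 ** (half if condition == "P" else -half))
        n = int(rng.poisson(mean))
        if locus.cls in HAIRPIN_CLASSES:
            n_star = int(rng.binomial(n, config.star_fraction)) if (n and locus.star_seq) else 0
            locus_counts[locus.id] = {"mature": n, "star": n_star}
            inserts.extend(("__" + locus.cls, locus.mature_seq) for _ in range(n))
            inserts.extend(("__" + locus.cls, locus.star_seq) for _ in range(n_star))
            clean_class_counts[locus.cls] = clean_class_counts.get(locus.cls, 0) + n + n_star
        else:
            locus_counts[locus.id] = {"mature": n, "star": 0}
            tlen = locus.end - locus.start
            for _ in range(n):
                for _try in range(100):
                    ln = int(rng.choice(bg_lengths, p=bg_probs))
                    ln = min(ln, tlen)
                    off = int(rng.integers(0, tlen - ln + 1))
                    frag = _transcript_slice(genome, locus, off, ln)
                    if _insert_ok(frag, a3, a5):
                        break
                else:
                    raise RuntimeError(f"cannot draw admissible fragment from {locus.id}")
                inserts.append(("__" + locus.cls, frag))
            clean_class_counts[locus.cls] = clean_class_counts.get(locus.cls, 0) + n

    n_planted = len(inserts)
    n_background = n_clean - n_planted
    if n_background < 0:
        raise ValueError("clean pool too small for the planted means; lower class fractions")
    clean_class_counts["unannotated"] = n_background

    # background reads from non-locus intervals
    bg = [iv for iv in manifest.background_intervals if iv[1] - iv[0] >= 31]
    bg_weights = np.array([e - s for s, e in bg], dtype=float)
    bg_weights /= bg_weights.sum()
    chrom_seq = genome[manifest.chrom]
    for _ in range(n_background):
        for _try in range(100):
            s, e = bg[int(rng.choice(len(bg), p=bg_weights))]
            ln = int(rng.choice(bg_lengths, p=bg_probs))
            if e - s < ln:
                continue
            off = int(rng.integers(s, e - ln + 1))
            frag = chrom_seq[off : off + ln]
            if _insert_ok(frag, a3, a5):
                break
        else:
            raise RuntimeError("cannot draw admissible background read")
        inserts.append(("__unannotated", frag))

    # artifact reads
    def _rand_no_adapter(n: int) -> str:
        while True:
            seq = _rand_seq(rng, n)
            if a3[:6] not in seq and "N" not in seq:
                return seq

    reads_raw: list[tuple[str, str]] = []  # (category, full read)
    for cat, count in category_counts.items():
        for _ in range(count):
            if cat == "low_quality":
                seq = list(_rand_seq(rng, read_len))
                for p in rng.choice(read_len, size=int(rng.integers(1, 4)), replace=False):
                    seq[p] = "N"
                reads_raw.append((cat, "".join(seq)))
            elif cat == "adapter3_null":
                reads_raw.append((cat, _rand_no_adapter(read_len)))
            elif cat == "insert_null":
                read = (a3 + _rand_no_adapter(read_len))[:read_len]
                reads_raw.append((cat, read))
            elif cat == "adapter5_contaminant":
                while True:
                    ins = a5[-8:] + _rand_seq(rng, int(rng.integers(10, 17)))
                    if a3[:6] not in ins and ins.count("A") / len(ins) < 0.8:
                        break
                reads_raw.append((cat, (ins + a3)[:read_len]))
            elif cat == "polyA":
                while True:
                    ln = int(rng.integers(18, 31))
                    ins = "".join(
                        "A" if rng.random() < 0.9 else _rand_seq(rng, 1) for _ in range(ln)
                    )
                    if ins.count("A") / len(ins) >= 0.8 and a3[:6] not in ins \
                            and not ins.startswith(a5[-6:]):
                        break
                reads_raw.append((cat, (ins + a3)[:read_len]))
            elif cat == "too_short":
                while True:
                    ln = int(rng.integers(8, 18))
                    ins = _rand_seq(rng, ln)
                    if _insert_ok(ins, a3, a5):
                        break
                read = ins + a3
                if len(read) < read_len:
                    read += _rand_no_adapter(read_len - len(read))
                reads_raw.append((cat, read[:read_len]))

    for cat, ins in inserts:
        reads_raw.append((cat.lstrip("_"), (ins + a3)[:read_len]))

    # categories for the truth table; clean classes roll up correctly
    final_counts = dict(category_counts)
    final_counts.update(clean_class_counts)

    order = rng.permutation(len(reads_raw))
    reads = [
        SimRead(f"{condition}_{i:06d}", reads_raw[j][1], "I" * len(reads_raw[j][1]))
        for i, j in enumerate(order)
    ]
    truth = LibraryTruth(
        condition=condition,
        total=total,
        category_counts=final_counts,
        locus_counts=locus_counts,
    )
    manifest.library_totals[condition] = total
    manifest.true_category_counts[condition] = final_counts
    manifest.locus_counts[condition] = locus_counts
    return reads, truth


# ---------------------------------------------------------------------------
# dataset convenience wrapper and writers


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    manifest: GroundTruthManifest
    reads: dict[str, list[SimRead]]


def simulate_dataset(config: SimulationConfig, outdir: Optional[Path] = None) -> SimulatedDataset:
    """Generate genome + both libraries; optionally write all files.

    Files written: genome.fa, reads_D.fastq, reads_P.fastq, mature.fa,
    hairpin.fa (miRBase flavour, U alphabet), features.bed, loci.bed,
    manifest.tsv.
    """
    genome, manifest = build_toy_genome(config)
    reads = {}
    for cond in ("D", "P"):
        reads[cond], _ = simulate_library(genome, manifest, config, cond)
    ds = SimulatedDataset(config, genome, manifest, reads)
    if outdir is not None:
        write_dataset(ds, Path(outdir))
    return ds


def write_dataset(ds: SimulatedDataset, outdir: Path) -> dict[str, Path]:
    from .io import write_bed6, write_fasta, write_fastq

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "reads_D": outdir / "reads_D.fastq",
        "reads_P": outdir / "reads_P.fastq",
        "mature": outdir / "mature.fa",
        "hairpin": outdir / "hairpin.fa",
        "features": outdir / "features.bed",
        "loci": outdir / "loci.bed",
        "manifest": outdir / "manifest.tsv",
    }
    write_fasta(paths["genome"], [(ds.manifest.chrom, ds.genome[ds.manifest.chrom])])
    for cond in ("D", "P"):
        write_fastq(paths[f"reads_{cond}"], ds.reads[cond])

    def _rna(seq: str) -> str:
        return seq.replace("T", "U")

    mature_recs, hairpin_recs = [], []
    known = ds.manifest.by_class("known_mirna")
    for i, locus in enumerate(known, start=1):
        acc = f"CMI{i:07d}"
        hairpin_recs.append((f"{locus.id} {acc}", _rna(locus.precursor_seq)))
        mature_recs.append((f"{locus.mature_name} {acc}M1", _rna(locus.mature_seq)))
        mature_recs.append((f"{locus.star_name} {acc}M2", _rna(locus.star_seq)))
    write_fasta(paths["mature"], mature_recs)
    write_fasta(paths["hairpin"], hairpin_recs)

    feat_rows = [
        (l.chrom, l.start, l.end, l.cls, 0, l.strand)
        for l in ds.manifest.loci
        if l.cls in FEATURE_LOCUS_CLASSES
    ]
    write_bed6(paths["features"], feat_rows)
    write_bed6(
        paths["loci"],
        [(l.chrom, l.start, l.end, f"{l.id}|{l.cls}", 0, l.strand) for l in ds.manifest.loci],
    )
    with open(paths["manifest"], "w") as fh:
        fh.write("id\tclass\tchrom\tstart\tend\tstrand\tbase_mean\tlog2fc\t"
                 "mature_seq\tstar_seq\tmature_name\tstar_name\tviolated\n")
        for l in ds.manifest.loci:
            fh.write(
                f"{l.id}\t{l.cls}\t{l.chrom}\t{l.start}\t{l.end}\t{l.strand}\t"
                f"{l.base_mean:.3f}\t{l.log2fc}\t{l.mature_seq}\t{l.star_seq}\t"
                f"{l.mature_name}\t{l.star_name}\t{l.violated or ''}\n"
            )
    return paths
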