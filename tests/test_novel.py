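"""Novel-miRNA prediction: candidate filtering, feature extraction, the
seven criteria with their exact boundaries, and planted-hairpin recovery."""

import pytest

from caprimir.fold import fold_mfe
from caprimir.mapping import Alignment, reverse_complement
from caprimir.novel import (
    CriteriaThresholds,
    HairpinFeatures,
    apply_criteria,
    excise_windows,
    extract_candidates,
    extract_features,
)
from caprimir.worked_example import LET7A_MATURE

GENOME = None


def _toy_genome():
    import random

    rng = random.Random(21)
    return {"chr1": "".join(rng.choice("ACGT") for _ in range(2000))}


def test_candidate_filters():
    genome = _toy_genome()
    tag = genome["chr1"][500:522]
    unique = [Alignment("chr1", 500, "+", 0)]
    multi = unique + [Alignment("chr1", 900, "+", 1)]
    tags = {tag: 20}
    cats = {tag: "unannotated"}
    # low abundance excluded
    assert extract_candidates({tag: 4}, {tag: unique}, cats, genome) == []
    # multi-locus excluded
    assert extract_candidates(tags, {tag: multi}, cats, genome) == []
    # annotated excluded
    assert extract_candidates(tags, {tag: unique}, {tag: "rRNA"}, genome) == []
    # survivor gets two windows with the tag at opposite ends
    cands = extract_candidates(tags, {tag: unique}, cats, genome)
    assert len(cands) == 1 and len(cands[0].windows) == 2
    w1, w2 = cands[0].windows
    assert w1.tag_span == (0, 22) and w1.sequence.startswith(tag)
    assert w2.tag_span == (70, 92) and w2.sequence.endswith(tag)


def test_windows_are_strand_aware():
    genome = _toy_genome()
    aln = Alignment("chr1", 600, "-", 0)
    tag = reverse_complement(genome["chr1"][600:622])
    w1, w2 = excise_windows(tag, aln, genome)
    assert w1.sequence == reverse_complement(genome["chr1"][530:622])
    assert w1.tag_span == (0, 22)
    assert w2.sequence == reverse_complement(genome["chr1"][600:692])
    assert w2.tag_span == (70, 92)


def test_windows_clipped_at_chromosome_ends():
    genome = _toy_genome()
    tag = genome["chr1"][:20]
    w1, w2 = excise_windows(tag, Alignment("chr1", 0, "+", 0), genome)
    assert w2.start == 0 and len(w2.sequence) == 20


def test_features_of_a_perfect_hairpin():
    arm = "GCATCGGATGCCATGCATGCATGCA"  # 25 nt
    seq = arm + "GCTA" + reverse_complement(arm)
    structure = fold_mfe(seq)
    feats = extract_features(structure, (0, 22))
    assert feats.n_stem_pairs == 25
    assert feats.loop_length == 4
    assert feats.max_bulge == 0
    assert feats.hairpin_length == 54
    assert feats.mature_in_stem_pct == 100.0


def test_let7a_au_content_worked_example():
    """A+U of the reference let-7a mature: 14 of 22 bases = 63.6%."""
    seq = LET7A_MATURE.upper().replace("U", "T")
    padded = seq + "GCGC" * 8  # any window; only the mature span matters
    structure = fold_mfe(padded)
    feats = extract_features(structure, (0, 22))
    assert round(feats.mature_au_pct, 1) == 63.6


def test_mature_across_loop_scores_below_80():
    stem = "GCATCGGATGCCATGCATGCATGCAT"  # 26 nt
    seq = stem + "ATGCGTAC" + reverse_complement(stem)
    structure = fold_mfe(seq)
    feats = extract_features(structure, (16, 38))  # spans the terminal loop
    assert feats.mature_in_stem_pct < 80.0


def test_zero_pair_structure_fails_criteria():
    structure = fold_mfe("A" * 30)
    feats = extract_features(structure, (0, 22))
    assert feats.n_stem_pairs == 0 and feats.loop_length is None
    assert not apply_criteria(feats).overall


BASE = dict(n_stem_pairs=25, loop_length=4, max_bulge=0, hairpin_length=54,
            mature_in_stem_pct=100.0, mature_au_pct=50.0, mfe=-40.0)


@pytest.mark.parametrize(
    "override, failing",
    [
        ({}, None),
        ({"n_stem_pairs": 17}, "c1"),
        ({"max_bulge": 19}, "c2"),
        ({"mfe": -20.0}, "c3"),           # "under -20" is strict
        ({"mfe": -19.9}, "c3"),
        ({"mature_in_stem_pct": 79.9}, "c4"),
        ({"hairpin_length": 52}, "c5"),
        ({"loop_length": 23}, "c6"),
        ({"mature_au_pct": 25.0}, "c7"),
        ({"mature_au_pct": 71.0}, "c7"),
    ],
)
def test_criteria_boundaries(override, failing):
    feats = HairpinFeatures(**{**BASE, **override})
    verdict = apply_criteria(feats)
    if failing is None:
        assert verdict.overall
    else:
        assert not verdict.overall
        failures = [f"c{i+1}" for i, ok in enumerate(verdict) if not ok]
        assert failures == [failing]


def test_boundary_values_that_still_pass():
    feats = HairpinFeatures(**{**BASE, "n_stem_pairs": 18, "max_bulge": 18,
                               "hairpin_length": 53, "loop_length": 22,
                               "mature_in_stem_pct": 80.0, "mature_au_pct": 30.0})
    assert apply_criteria(feats).overall
    feats70 = HairpinFeatures(**{**BASE, "mature_au_pct": 70.0})
    assert apply_criteria(feats70).overall


def test_criteria_monotone_in_stem_strength():
    """Adding a terminal pair (more pairs, longer hairpin) never flips c1 or
    c5 from pass to fail."""
    for pairs in range(18, 30):
        before = apply_criteria(HairpinFeatures(**{**BASE, "n_stem_pairs": pairs,
                                                   "hairpin_length": 2 * pairs + 4}))
        after = apply_criteria(HairpinFeatures(**{**BASE, "n_stem_pairs": pairs + 1,
                                                  "hairpin_length": 2 * pairs + 6}))
        assert (not before.c1 or after.c1) and (not before.c5 or after.c5)


def test_configurable_thresholds():
    feats = HairpinFeatures(**{**BASE, "n_stem_pairs": 15})
    assert not apply_criteria(feats).overall
    assert apply_criteria(feats, CriteriaThresholds(min_stem_pairs=15)).overall


def test_planted_hairpins_recovered_and_decoys_rejected(pipeline_run):
    ds, result = pipeline_run
    planted = ds.manifest.by_class("novel_hairpin")
    recovered = sum(
        any(p.window.start < l.end and p.window.end > l.start for p in result.novel)
        for l in planted
    )
    assert recovered >= 9
    decoy_hits = [
        p.novel_id
        for p in result.novel
        for l in ds.manifest.by_class("decoy_hairpin")
        if p.window.start < l.end and p.window.end > l.start
    ]
    assert decoy_hits == []
    # ids are assigned in descending total count
    totals = [p.total_count for p in result.novel]
    assert totals == sorted(totals, reverse=True)


def test_decoys_fail_their_named_criterion(dataset):
    """Folding the hairpin-bearing excision window of each decoy's mature
    tag reproduces the designed violation."""
    ds, _dir = dataset
    genome = ds.genome
    for locus in ds.manifest.by_class("decoy_hairpin"):
        aln = Alignment(locus.chrom, locus.mature_start,
                        locus.strand, 0)
        tag = locus.mature_seq
        windows = excise_windows(tag, aln, genome)
        verdicts = []
        for w in windows:
            feats = extract_features(fold_mfe(w.sequence), w.tag_span)
            verdicts.append(apply_criteria(feats))
        assert all(not v.overall for v in verdicts)
        idx = int(locus.violated[1]) - 1
        assert not verdicts[0][idx], locus.id
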