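"""Conserved-miRNA matching: reference loading, isomiR end tolerance, arm
naming, count tables, and star-strand asymmetry on synthetic data."""

import pytest

from caprimir.known import (
    ConservedMatcher,
    Mature,
    MiRBaseEntry,
    assign_arm,
    count_table,
    load_mirbase,
    match_conserved,
)

PREC = "GGACT" + "ACGTGCATGCCATGCATGACTG" + "GCTTAGCA" + "CAGTCATGCATGGCTTGCACGT" + "AGTCC"
MATURE = "ACGTGCATGCCATGCATGACTG"          # offset 5, len 22
STAR = "CAGTCATGCATGGCTTGCACGT"            # offset 35

ENTRY = MiRBaseEntry(
    "cap-mir-9",
    PREC,
    (Mature("cap-miR-9", MATURE, 5), Mature("cap-miR-9*", STAR, 35)),
)


def test_mature_must_sit_at_recorded_offset():
    with pytest.raises(ValueError):
        MiRBaseEntry("x", PREC, (Mature("x", MATURE, 6),))


def test_exact_mature_matches_with_zero_shift():
    m = match_conserved(MATURE, [ENTRY])
    assert m is not None
    assert (m.mature.label, m.start, m.mismatches, m.shift) == ("cap-miR-9", 5, 0, 0)


def test_three_prime_extension_within_tolerance():
    tag = PREC[5:29]  # mature + 2 nt deeper into the precursor
    m = match_conserved(tag, [ENTRY])
    assert m is not None and m.shift == 2 and m.mature.label == "cap-miR-9"


def test_shift_beyond_tolerance_rejected():
    tag = PREC[5:30]  # 3 nt beyond the mature end
    assert match_conserved(tag, [ENTRY]) is None


def test_loop_only_fragment_does_not_match():
    tag = PREC[26:46]  # loop-centred fragment
    assert match_conserved(tag, [ENTRY]) is None


def test_star_arm_matches_star_entry():
    m = match_conserved(STAR, [ENTRY])
    assert m is not None and m.mature.label == "cap-miR-9*"


@pytest.mark.parametrize(
    "label, arm",
    [
        ("miR-126*", "miRNA*"),
        ("let-7a", "miRNA"),
        ("miR-199a-3p", "miRNA-3p"),
        ("cap-miR-3-5p", "miRNA-5p"),
    ],
)
def test_arm_naming_convention(label, arm):
    assert assign_arm(label) == arm


def test_count_table_tallies():
    tag2 = PREC[5:29]
    m1 = match_conserved(MATURE, [ENTRY])
    m2 = match_conserved(tag2, [ENTRY])
    table, summary = count_table({MATURE: (3, m1), tag2: (5, m2)})
    assert summary["detected_mirnas"] == 1
    assert summary["unique_tags_matched"] == 2
    assert summary["total_reads_matched"] == 8
    row = table.iloc[0]
    assert row["unique_tags"] == 2 and row["total_reads"] == 8


def test_empty_count_table():
    table, summary = count_table({})
    assert table.empty and summary["detected_mirnas"] == 0


def test_fast_matcher_agrees_with_scan(dataset):
    """The exact-lookup fast path returns the same matches (including
    tie-breaks) as the reference scanning implementation."""
    ds, data_dir = dataset
    entries = load_mirbase(data_dir / "mature.fa", data_dir / "hairpin.fa")
    matcher = ConservedMatcher(entries)
    probes = []
    for locus in ds.manifest.by_class("known_mirna")[:10]:
        probes += [locus.mature_seq, locus.star_seq, locus.mature_seq[:-2],
                   locus.mature_seq[2:] + "AC"]
    for tag in probes:
        fast = matcher.match(tag)
        slow = match_conserved(tag, entries)
        if slow is None:
            assert fast is None
        else:
            assert fast is not None
            assert (fast.entry.name, fast.mature.label, fast.start) == (
                slow.entry.name, slow.mature.label, slow.start)


def test_reference_roundtrip_and_u_normalization(dataset):
    ds, data_dir = dataset
    entries = load_mirbase(data_dir / "mature.fa", data_dir / "hairpin.fa")
    assert len(entries) == len(ds.manifest.by_class("known_mirna"))
    by_name = {e.name: e for e in entries}
    for locus in ds.manifest.by_class("known_mirna"):
        entry = by_name[locus.id]
        assert entry.precursor_seq == locus.precursor_seq  # U re-normalized to T
        assert {m.label for m in entry.matures} == {locus.mature_name, locus.star_name}


def test_planted_reads_all_assigned_to_their_source(pipeline_run):
    ds, result = pipeline_run
    for cond in ("D", "P"):
        truth = ds.manifest.locus_counts[cond]
        table = result.known_tables[cond].set_index("mirna")["total_reads"].to_dict()
        for locus in ds.manifest.by_class("known_mirna"):
            assert table.get(locus.mature_name, 0) == truth[locus.id]["mature"]
            assert table.get(locus.star_name, 0) == truth[locus.id]["star"]


def test_star_reads_are_rarer_than_mature(pipeline_run):
    """With star_fraction < 0.5 each detected star is less abundant than its
    mature partner, mirroring passenger-strand degradation."""
    ds, result = pipeline_run
    for cond in ("D", "P"):
        table = result.known_tables[cond].set_index("mirna")["total_reads"].to_dict()
        compared = 0
        for locus in ds.manifest.by_class("known_mirna"):
            if locus.star_name in table and locus.mature_name in table:
                assert table[locus.star_name] < table[locus.mature_name]
                compared += 1
        assert compared > 10


def test_matched_reads_equal_known_category_reads(pipeline_run):
    _ds, result = pipeline_run
    for cond in ("D", "P"):
        ann = result.annotation_summaries[cond].set_index("category")
        known_reads = int(ann.loc["known_miRNA", "total_reads"])
        assert result.known_summaries[cond]["total_reads_matched"] == known_reads
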