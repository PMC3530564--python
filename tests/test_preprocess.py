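"""Read cleaning: category ladder, count conservation, collapsing, and the
library accounting identities."""

from collections import Counter

import pytest

from caprimir.preprocess import (
    CleanTag,
    classify_read,
    clean_library,
    length_distribution,
)
from caprimir.worked_example import CLEAN_READS, RAW_READS

A3 = "TCGTATGCCGTCTTCTGCTTG"
A5 = "GTTCAGAGTTCTACAGTCCGACGATC"
INSERT22 = "ACGTGCATGCCATGCATGACTG"


def _read(insert, pad=""):
    return (insert + A3 + pad)[:36]


@pytest.mark.parametrize(
    "sequence, expected",
    [
        (_read(INSERT22), "clean"),                       # 22-nt insert, trimmed
        ("ACGTGCATGCCATGCATGACTGACGTGCATGCCATG", "adapter3_null"),  # no adapter
        (_read(A5[-8:] + "ACGTGCATGC"), "adapter5_contaminant"),
        (_read("AAAAAAAAAAAAAAAAAAAA"), "polyA"),
        (_read("ACGTGCATGCCATGCA") + "G" * 36, "too_short"),  # 16-nt insert
        ((A3 + "ACGTACGTACGTACG")[:36], "insert_null"),
        (_read(INSERT22)[:20] + "N" + _read(INSERT22)[21:], "low_quality"),
        (_read("ACGTGCATGCCATGCATGACTGACGTGCATGC"), "adapter3_null"),  # 32-nt insert
    ],
)
def test_category_ladder(sequence, expected):
    cat, insert = classify_read(sequence, A3, A5)
    assert cat == expected
    if expected == "clean":
        assert insert == INSERT22


def test_clean_read_returns_trimmed_insert():
    cat, insert = classify_read(_read(INSERT22), A3, A5)
    assert (cat, insert) == ("clean", INSERT22)


def test_empty_read_is_an_error():
    with pytest.raises(ValueError):
        classify_read("", A3, A5)


def test_already_trimmed_inserts_are_not_retrimmed():
    """Cleaning a bare insert (no adapter) lands in adapter3_null, which
    guards against accidentally double-trimming pre-cleaned input."""
    cat, _ = classify_read("ACGTGCATGCCATGCATGACTG", A3, A5)
    assert cat == "adapter3_null"


def test_collapse_matches_brute_force_and_conserves_counts():
    inserts = ["ACGTGCATGCCATGCATGACTG", "TTGCAGCATGCCATGCATGACT", "ACGTGCATGCCATGCATGACTG"]
    reads = [(f"r{i}", _read(s)) for i, s in enumerate(inserts * 7)]
    reads.append(("bad", "ACGT" * 9))  # no adapter
    tags, report = clean_library(reads, A3, A5)
    assert report.raw_reads == 22
    assert report.clean_reads == 21
    assert report.adapter3_null == 1
    expected = Counter(inserts * 7)
    assert {t.sequence: t.count for t in tags} == dict(expected)
    assert sum(t.count for t in tags) == report.clean_reads
    report.check_identity()


def test_empty_library_gives_all_zero_report():
    tags, report = clean_library([], A3, A5)
    assert tags == []
    assert report.raw_reads == 0 and report.clean_reads == 0


def test_published_clean_percentage_reproduced():
    """Clean-read percentage recomputed from the published library counts."""
    pct = 100.0 * CLEAN_READS["D"] / RAW_READS["D"]
    assert round(pct, 2) == 94.55
    pct_p = 100.0 * CLEAN_READS["P"] / RAW_READS["P"]
    assert round(pct_p, 2) == 90.57


def test_length_distribution_sums_and_trivial_case():
    assert length_distribution([CleanTag("A" * 22, 7)]) == {22: 7}
    tags = [CleanTag("G" * 18, 3), CleanTag("C" * 22, 5), CleanTag("T" * 22, 2)]
    hist = length_distribution(tags)
    assert hist == {18: 3, 22: 7}
    assert sum(hist.values()) == sum(t.count for t in tags)


def test_qc_report_matches_generator_manifest_exactly(pipeline_run):
    """Every artifact class and the clean total agree with the planted truth,
    read for read, in both libraries."""
    ds, result = pipeline_run
    artifact = ("low_quality", "adapter3_null", "insert_null",
                "adapter5_contaminant", "polyA", "too_short")
    for cond in ("D", "P"):
        truth = ds.manifest.true_category_counts[cond]
        qc = result.qc[cond]
        assert qc.raw_reads == ds.manifest.library_totals[cond]
        assert qc.raw_reads - qc.high_quality == truth["low_quality"]
        assert qc.adapter3_null == truth["adapter3_null"]
        assert qc.insert_null == truth["insert_null"]
        assert qc.adapter5_contaminant == truth["adapter5_contaminant"]
        assert qc.polyA == truth["polyA"]
        assert qc.shorter_than_18 == truth["too_short"]
        clean_truth = sum(v for k, v in truth.items() if k not in artifact)
        assert qc.clean_reads == clean_truth


def test_synthetic_length_mode_is_22(pipeline_run):
    _ds, result = pipeline_run
    for cond in ("D", "P"):
        hist = length_distribution(result.tags[cond])
        assert max(hist, key=hist.get) == 22
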