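"""Synthetic-data generator: determinism, conservation, construction
guarantees for planted hairpins and decoys, and artifact-fraction sanity."""

import math

import numpy as np
import pytest

from caprimir.fold import fold_mfe
from caprimir.novel import apply_criteria, extract_features
from caprimir.simulate import (
    SimulationConfig,
    build_toy_genome,
    construct_passing_hairpin,
    simulate_library,
)

from conftest import tiny_config


def test_same_seed_reproduces_everything_bytewise():
    cfg = tiny_config(seed=13)
    g1, m1 = build_toy_genome(cfg)
    g2, m2 = build_toy_genome(cfg)
    assert g1 == g2
    assert [(l.id, l.start, l.end, l.strand, l.mature_seq) for l in m1.loci] == [
        (l.id, l.start, l.end, l.strand, l.mature_seq) for l in m2.loci
    ]
    r1, t1 = simulate_library(g1, m1, cfg, "D")
    r2, t2 = simulate_library(g2, m2, cfg, "D")
    assert r1 == r2
    assert t1.category_counts == t2.category_counts


def test_different_seed_changes_the_genome():
    g1, _ = build_toy_genome(tiny_config(seed=13))
    g2, _ = build_toy_genome(tiny_config(seed=14))
    assert g1 != g2


def test_capacity_error():
    cfg = tiny_config(genome_length=200)
    with pytest.raises(ValueError, match="capacity"):
        build_toy_genome(cfg)


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(frac_short=1.2).validate()
    with pytest.raises(ValueError):
        SimulationConfig(frac_short=0.6, frac_low_quality=0.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(star_fraction=0.0).validate()


def test_hairpin_constructor_precondition():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        construct_passing_hairpin(rng, 19)
    with pytest.raises(ValueError):
        construct_passing_hairpin(rng, 25)


def test_constructed_hairpins_pass_criteria():
    """Repeated draws all satisfy the seven criteria (checker as oracle)."""
    rng = np.random.default_rng(123)
    for _ in range(20):
        seq, m_span, s_span = construct_passing_hairpin(rng, 22)
        feats = extract_features(fold_mfe(seq), m_span)
        assert apply_criteria(feats).overall
        # star is the annotated partner arm, same length as the mature
        assert s_span[1] - s_span[0] == 22
        assert m_span == (5, 27)


def test_category_counts_sum_to_library_total(pipeline_run):
    ds, _result = pipeline_run
    for cond in ("D", "P"):
        counts = ds.manifest.true_category_counts[cond]
        assert sum(counts.values()) == ds.manifest.library_totals[cond]


def test_every_novel_locus_passes_and_decoys_fail_by_construction(dataset):
    ds, _dir = dataset
    for locus in ds.manifest.by_class("novel_hairpin"):
        assert locus.expected_verdict is not None and locus.expected_verdict.overall
    for locus in ds.manifest.by_class("decoy_hairpin"):
        assert locus.expected_verdict is not None and not locus.expected_verdict.overall
        assert locus.violated in {"c1", "c2", "c3", "c4", "c5", "c6", "c7"}


def test_artifact_fractions_within_sampling_error(dataset):
    """Multinomial draws around the configured artifact fractions (4 sigma)."""
    ds, _dir = dataset
    cfg = ds.config
    n = cfg.reads_per_library
    for cond in ("D", "P"):
        counts = ds.manifest.true_category_counts[cond]
        for key, frac in cfg.artifact_fractions().items():
            sigma = math.sqrt(n * frac * (1 - frac))
            assert abs(counts[key] - n * frac) <= 4 * sigma + 1, (cond, key)


def test_star_reads_track_star_fraction(dataset):
    """Aggregate star counts are ~5% of mature counts (4 sigma binomial)."""
    ds, _dir = dataset
    cfg = ds.config
    for cond in ("D", "P"):
        mature = star = 0
        for locus in ds.manifest.loci:
            if locus.cls in ("known_mirna", "novel_hairpin", "decoy_hairpin"):
                lc = ds.manifest.locus_counts[cond][locus.id]
                if locus.star_seq:
                    mature += lc["mature"]
                    star += lc["star"]
        sigma = math.sqrt(mature * cfg.star_fraction * (1 - cfg.star_fraction))
        assert abs(star - mature * cfg.star_fraction) <= 4 * sigma


def test_planted_fold_change_scales_condition_means(dataset):
    """A +2 planted log2fc yields ~4x the reads at peak lactation."""
    ds, _dir = dataset
    for locus in ds.manifest.by_class("known_mirna"):
        if locus.log2fc == 0.0 or locus.base_mean < 200:
            continue
        d = ds.manifest.locus_counts["D"][locus.id]["mature"]
        p = ds.manifest.locus_counts["P"][locus.id]["mature"]
        ratio = p / max(d, 1)
        expected = 2.0 ** locus.log2fc
        assert 0.5 * expected < ratio < 2.0 * expected, locus.id


def test_reads_trace_back_to_manifest(dataset):
    """Every mature read sequence is the planted mature of its locus and the
    locus coordinates contain it on the recorded strand."""
    from caprimir.mapping import reverse_complement

    ds, _dir = dataset
    genome = ds.genome[ds.manifest.chrom]
    for locus in ds.manifest.by_class("novel_hairpin"):
        g = genome[locus.mature_start : locus.mature_end]
        if locus.strand == "-":
            g = reverse_complement(g)
        assert g == locus.mature_seq
        assert locus.start <= locus.mature_start < locus.mature_end <= locus.end
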