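"""End-to-end pipeline orchestration and the two-library overlap summary.

``run_pipeline`` wires the stage modules together over files on disk:
clean both libraries, map the union of tags, match against the known-miRNA
reference, annotate, quantify known miRNAs, predict novel miRNAs from
unannotated unique tags (>= 5 reads, pooled over both libraries), run the
differential-expression comparison, and write every report as TSV into the
run directory.  Runs are deterministic: identical inputs and configuration
give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Optional

import pandas as pd
import yaml

from . import io as cio
from .annotation import FeatureSet, annotate_tag, summarize_categories
from .diffexp import diff_table, diff_table_frame
from .known import ConservedMatcher, count_table, load_mirbase
from .mapping import build_index, classify_mapping, map_tag
from .novel import (
    CriteriaThresholds,
    extract_candidates,
    predict_novel,
    predictions_frame,
)
from .preprocess import CleanTag, clean_library, length_distribution

log = logging.getLogger("caprimir")

__all__ = ["PipelineConfig", "PipelineResult", "OverlapSummary", "overlap_summary", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one run; defaults are the published values."""

    reads_d: Path
    reads_p: Path
    genome_fasta: Path
    mature_fa: Path
    hairpin_fa: Path
    features_bed: Path
    outdir: Path
    adapter_3p: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter_5p: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_novel_count: int = 5       # "fewer than five reads" exclusion
    max_mismatch: int = 1          # genome mapping tolerance
    mirna_max_mismatch: int = 0    # reference matching
    mirna_max_shift: int = 2
    criteria: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    pvalue_variant: str = "two-sided"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        crit = raw.pop("criteria", None)
        cfg = cls(**{k: Path(v) if k.endswith(("_d", "_p", "_fasta", "_fa", "_bed")) or k == "outdir"
                     else v for k, v in raw.items()})
        if crit:
            cfg.criteria = CriteriaThresholds(**crit)
        return cfg

    def validate(self) -> None:
        for name in ("reads_d", "reads_p", "genome_fasta", "mature_fa", "hairpin_fa", "features_bed"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


class OverlapSummary(NamedTuple):
    """Sequence-level overlap between the two libraries.

    Total-read percentages (common + P-specific + D-specific) sum to 100;
    ``common_unique_pct`` is over the union of unique tags.
    """

    common_total_pct: float
    p_specific_total_pct: float
    d_specific_total_pct: float
    common_unique_pct: float


def overlap_summary(tags_d: Mapping[str, int], tags_p: Mapping[str, int]) -> OverlapSummary:
    """Common/specific read and tag fractions of two collapsed libraries."""
    set_d, set_p = set(tags_d), set(tags_p)
    common = set_d & set_p
    union = set_d | set_p
    total = sum(tags_d.values()) + sum(tags_p.values())
    if total == 0:
        return OverlapSummary(0.0, 0.0, 0.0, 0.0)
    common_reads = sum(tags_d[t] for t in common) + sum(tags_p[t] for t in common)
    p_only = sum(tags_p[t] for t in set_p - common)
    d_only = sum(tags_d[t] for t in set_d - common)
    return OverlapSummary(
        common_total_pct=100.0 * common_reads / total,
        p_specific_total_pct=100.0 * p_only / total,
        d_specific_total_pct=100.0 * d_only / total,
        common_unique_pct=100.0 * len(common) / len(union) if union else 0.0,
    )


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    qc: dict[str, object]
    tags: dict[str, list[CleanTag]]
    alignments: dict[str, list]
    categories: dict[str, str]
    known_tables: dict[str, pd.DataFrame]
    known_summaries: dict[str, dict]
    novel: list
    diffexp: list
    diffexp_summary: dict
    overlap: OverlapSummary
    annotation_summaries: dict[str, pd.DataFrame]


def _tag_counts(tags: list[CleanTag]) -> dict[str, int]:
    return {t.sequence: t.count for t in tags}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage over the configured inputs; see the module docstring."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> PipelineResult:
    log.info("pipeline start; config: %s", {
        k: str(v) for k, v in vars(config).items()
    })

    # 1. clean + collapse
    tags: dict[str, list[CleanTag]] = {}
    qc: dict[str, object] = {}
    for cond, path in (("D", config.reads_d), ("P", config.reads_p)):
        reader = cio.read_fastq if str(path).endswith(("fastq", "fq")) else cio.read_fasta
        tags[cond], report = clean_library(reader(path), config.adapter_3p, config.adapter_5p)
        qc[cond] = report
        cio.write_qc_report(outdir / f"qc_{cond}.tsv", report)
        cio.write_collapsed_tags(outdir / f"tags_{cond}.fa", tags[cond])
        log.info("library %s: raw=%d clean=%d unique=%d", cond,
                 report.raw_reads, report.clean_reads, len(tags[cond]))

    # length distribution over both libraries
    hist_frames = []
    for cond in ("D", "P"):
        hist = length_distribution(tags[cond])
        hist_frames.append(pd.DataFrame(
            {"length": list(hist), "reads": list(hist.values()), "library": cond}
        ))
    pd.concat(hist_frames).to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)

    # 2. map the union of tags
    genome = {name.split()[0]: seq.upper() for name, seq in cio.read_fasta(config.genome_fasta)}
    index = build_index(genome)
    counts = {cond: _tag_counts(tags[cond]) for cond in ("D", "P")}
    union_tags = sorted(set(counts["D"]) | set(counts["P"]))
    alignments = {tag: map_tag(tag, index, config.max_mismatch) for tag in union_tags}
    mapped = sum(1 for t in union_tags if alignments[t])
    log.info("mapping: %d/%d unique tags mapped", mapped, len(union_tags))
    bed_rows = []
    for tag in union_tags:
        for aln in alignments[tag]:
            bed_rows.append((aln.chrom, aln.start, aln.start + len(tag), tag, aln.mismatches, aln.strand))
    cio.write_bed6(outdir / "alignments.bed", sorted(bed_rows))

    # 3. known-miRNA matching and annotation
    entries = load_mirbase(config.mature_fa, config.hairpin_fa)
    matcher = ConservedMatcher(entries, config.mirna_max_mismatch, config.mirna_max_shift)
    matches = {tag: m for tag in union_tags if (m := matcher.match(tag)) is not None}
    features = FeatureSet.from_bed(config.features_bed)
    categories = {
        tag: annotate_tag(tag, alignments[tag], features, tag in matches)
        for tag in union_tags
    }
    ann_summaries = {}
    for cond in ("D", "P"):
        cond_cats = {t: categories[t] for t in counts[cond]}
        summary = summarize_categories(cond_cats, counts[cond])
        ann_summaries[cond] = summary
        summary.to_csv(outdir / f"annotation_{cond}.tsv", sep="\t", index=False)

    # 4. per-library known-miRNA count tables
    known_tables, known_summaries = {}, {}
    for cond in ("D", "P"):
        assignments = {
            t: (counts[cond][t], matches[t]) for t in counts[cond] if t in matches
        }
        table, summary = count_table(assignments)
        known_tables[cond], known_summaries[cond] = table, summary
        table.to_csv(outdir / f"known_mirnas_{cond}.tsv", sep="\t", index=False)
        log.info("known miRNAs %s: detected=%d precursors=%d reads=%d", cond,
                 summary["detected_mirnas"], summary["precursors_hit"],
                 summary["total_reads_matched"])

    # 5. novel prediction on pooled counts
    pooled = {t: counts["D"].get(t, 0) + counts["P"].get(t, 0) for t in union_tags}
    candidates = extract_candidates(
        pooled, alignments, categories, genome, config.min_novel_count
    )
    novel = predict_novel(candidates, counts["D"], counts["P"], config.criteria)
    predictions_frame(novel).to_csv(outdir / "novel_mirnas.tsv", sep="\t", index=False)
    with open(outdir / "novel_structures.txt", "w") as fh:
        for p in novel:
            fh.write(f">{p.novel_id}\n{p.window.sequence}\n"
                     f"{p.structure.dot_bracket} ({p.structure.mfe:.2f})\n")
    cio.write_fasta(outdir / "novel_precursors.fa",
                    [(p.novel_id, p.window.sequence) for p in novel])
    log.info("novel prediction: %d candidates, %d predicted", len(candidates), len(novel))

    # 6. differential expression over known matures + novel ids
    de_counts = {"D": {}, "P": {}}
    for cond in ("D", "P"):
        for t, (_c, m) in ((t, (counts[cond][t], matches[t])) for t in counts[cond] if t in matches):
            label = matches[t].mature.label
            de_counts[cond][label] = de_counts[cond].get(label, 0) + counts[cond][t]
    for p in novel:
        de_counts["D"][p.novel_id] = p.count_d
        de_counts["P"][p.novel_id] = p.count_p
    n1 = qc["D"].clean_reads
    n2 = qc["P"].clean_reads
    records, de_summary = diff_table(de_counts["D"], de_counts["P"], n1, n2,
                                     config.pvalue_variant)
    diff_table_frame(records).to_csv(outdir / "diffexp.tsv", sep="\t", index=False)
    log.info("diffexp: tested=%d up=%d down=%d", de_summary["tested"],
             de_summary["up"], de_summary["down"])

    # 7. overlap summary
    overlap = overlap_summary(counts["D"], counts["P"])
    pd.DataFrame([overlap._asdict()]).to_csv(outdir / "overlap.tsv", sep="\t", index=False)

    # accounting chain assertions
    for cond in ("D", "P"):
        assert sum(t.count for t in tags[cond]) == qc[cond].clean_reads
        assert int(ann_summaries[cond]["total_reads"].sum()) == qc[cond].clean_reads
    log.info("pipeline done")

    return PipelineResult(
        config=config,
        qc=qc,
        tags=tags,
        alignments=alignments,
        categories=categories,
        known_tables=known_tables,
        known_summaries=known_summaries,
        novel=novel,
        diffexp=records,
        diffexp_summary=de_summary,
        overlap=overlap,
        annotation_summaries=ann_summaries,
    )
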