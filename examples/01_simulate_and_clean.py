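"""Simulate a small two-library study and run read cleaning over it.

Generates a toy genome with planted miRNA loci, emits the dry-period (D)
library, cleans it, and prints the accounting report next to the generator's
ground truth — the two agree read for read.
"""

from caprimir.preprocess import clean_library, length_distribution
from caprimir.simulate import SimulationConfig, build_toy_genome, simulate_library

config = SimulationConfig(
    seed=1, reads_per_library=20_000, genome_length=60_000,
    n_known_mirnas=10, n_novel_hairpins=3, n_decoy_hairpins=3, n_ncrna_loci=1,
)
genome, manifest = build_toy_genome(config)
reads, truth = simulate_library(genome, manifest, config, condition="D")

tags, report = clean_library(
    ((r.id, r.sequence) for r in reads), config.adapter_3p, config.adapter_5p
)
print("category              observed      planted")
rows = [
    ("low quality (N)", report.raw_reads - report.high_quality, truth.category_counts["low_quality"]),
    ("3' adapter null", report.adapter3_null, truth.category_counts["adapter3_null"]),
    ("insert null", report.insert_null, truth.category_counts["insert_null"]),
    ("5' contaminant", report.adapter5_contaminant, truth.category_counts["adapter5_contaminant"]),
    ("polyA", report.polyA, truth.category_counts["polyA"]),
    ("shorter than 18 nt", report.shorter_than_18, truth.category_counts["too_short"]),
]
for name, obs, planted in rows:
    print(f"{name:20s} {obs:9d} {planted:12d}")
print(f"{'clean reads':20s} {report.clean_reads:9d}  "
      f"({report.percentage('clean_reads'):.2f}% of raw)")
print(f"unique tags after collapsing: {len(tags)}")

hist = length_distribution(tags)
mode = max(hist, key=hist.get)
print(f"insert length mode: {mode} nt "
      f"({100 * hist[mode] / sum(hist.values()):.1f}% of clean reads)")
# The mode sits at 22 nt, the canonical Dicer product length the generator
# plants; every accounting row matches the manifest exactly because reads
# are constructed to classify as their intended category.
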