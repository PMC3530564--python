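"""Reproduce the published two-library comparison for the headline miRNAs.

Takes the published raw counts and clean-read totals as inputs and
recomputes normalized expression (transcripts per million), log2 fold
change, and the Audic-Claverie exact p-value for each miRNA.
"""

from caprimir.diffexp import ac_log10_pvalue, fold_change, format_pvalue, normalize
from caprimir.worked_example import CLEAN_READS, DE_COUNTS

n1, n2 = CLEAN_READS["D"], CLEAN_READS["P"]
print(f"clean reads: dry={n1:,} peak={n2:,}\n")
print(f"{'miRNA':12s} {'D':>7s} {'P':>7s} {'D-NE':>10s} {'P-NE':>10s} "
      f"{'log2fc':>8s} {'p-value':>10s}")
for name, (x, y) in DE_COUNTS.items():
    x_ne, y_ne = normalize(x, n1), normalize(y, n2)
    fc = fold_change(x_ne, y_ne)
    log10p = ac_log10_pvalue(x, y, n1, n2, "two-sided")
    print(f"{name:12s} {x:7d} {y:7d} {x_ne:10.4f} {y_ne:10.4f} "
          f"{fc:8.4f} {format_pvalue(log10p):>10s}")
# miR-2887 roughly quadruples at peak lactation (log2fc 2.04, p ~ 1e-174);
# the let-7 family drops more than 10-fold during lactation.  Values with
# p-value "0" underflow double precision — the log10 scale stays exact.
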