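# Methods

This note documents the models, conventions and numerical choices behind
`caprimir`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Read cleaning

A raw read is an 18–30 nt insert followed by the 3′ sequencing adapter.
Classification walks a fixed ladder and each read lands in the first
matching category: reads containing `N` are *low quality* (the only quality
signal retained — Sanger quality strings are accepted but not interpreted);
the 3′ adapter is located as the **longest** prefix of the adapter sequence
(≥ 6 nt) found in the read, leftmost on ties, so a genuine full-length
adapter hit always beats a chance 6-mer further left; no hit (or an implied
insert longer than 30 nt) is *3′ adapter null*; a hit at position 0 is
*insert null*; an insert beginning with any ≥ 6 nt suffix of the 5′ adapter
is a *5′ contaminant*; an insert that is ≥ 80% A is *poly(A)*; an insert
under 18 nt is *too short*; everything else is clean. Clean inserts are
collapsed exactly (no mismatch tolerance) into unique tags with counts.

Accounting identities are enforced, not just reported: clean = high-quality
− (sum of artifact classes), and the collapsed tag counts sum to the clean
total. Percentages use raw reads as the denominator throughout (some
published accounting tables mix denominators between rows; we standardize
on raw).

## Mapping

The mapper is exhaustive at its stated tolerance: every genomic locus with
Hamming distance ≤ 1, on both strands, no indels. Completeness comes from
the pigeonhole principle — with at most one substitution, one of the tag's
two halves is exact, so looking up a k-mer seed (default k = 9, ≤ half the
minimum 18 nt tag) at the start of each half finds every candidate, which
is then verified against the reference. Uniqueness for downstream filters
counts distinct (chromosome, start) loci, so a palindromic locus hit on
both strands is still unique.

## Annotation

Sequence-similarity triage against ncRNA databases is replaced by
strand-agnostic interval overlap against a labelled feature set (BED), with
a fixed priority: known_miRNA first (so miRNA reads inside genes are not
absorbed by `exon`), then rRNA, tRNA, snRNA, snoRNA, scRNA, srpRNA, repeat,
exon, intron, and `unannotated` for everything else. One aligned base
inside a feature interval, at any of a tag's alignments, counts as overlap.
This makes annotation deterministic and database-version-free; the cost is
that fragments of ncRNAs *not* present in the feature set are called
unannotated.

## Conserved miRNA matching

A tag matches a reference entry when it aligns inside the precursor with at
most `max_mismatch` substitutions (default 0) and both of its ends fall
within `max_shift` (default 2) nt of a recorded mature's ends. This admits
templated isomiR end variation while rejecting loop fragments and star-arm
reads that do not overlap an annotated mature. Ties are broken by fewer
mismatches, then smaller total end shift, then lexicographic name, so a tag
is counted once even if it matches several families. Both tolerances are
configuration knobs because published pipelines rarely state them. Arm
categories come purely from reference naming (`*`, `-5p`, `-3p`, otherwise
plain `miRNA`). With exact matching the matcher precomputes all admissible
precursor substrings into a dictionary; the scanning implementation is kept
and cross-checked in tests.

## Hairpin folding

miRNA precursors are single stem-loops, so the folding model restricts the
structure space to chains of nested pairs: one terminal loop, no
multibranch loops. This makes the dynamic program a clean recursion over
candidate outermost pairs and — importantly for testing — makes exhaustive
enumeration of the entire structure space feasible for sequences up to
~30 nt, which is the independent oracle the DP is verified against.

Energy model (kcal/mol at 37 °C): Watson–Crick plus G·U pairs; a
21-parameter stacking table expanded to all 36 ordered pair combinations by
strand-reversal symmetry (Watson–Crick block follows the familiar
nearest-neighbour values; the wobble block uses plausible figures);
hairpin-loop penalty 5.0 + 1.08·ln(l/3); bulge penalty 3.8 + 1.08·ln(l)
with no stacking across the bulge; internal-loop penalty
2.0 + 1.08·ln((l₅+l₃)/2) + 0.55·|l₅−l₃|; minimum terminal loop 3 nt;
interior loops capped at 30 unpaired nt per side (structures beyond the cap
are disallowed in both the DP and the oracle). 1.08 ≈ 1.75 RT is the usual
logarithmic loop coefficient.

This is **not** an Mfold/Turner implementation: absolute free energies are
comparable in scale (a 20-bp stem folds well below −20 kcal/mol) but
published Mfold values for real precursors are not reproduced and are never
used as targets. Ties are resolved deterministically: lower energy, then
fewer pairs, then lexicographically smallest dot-bracket.

## The seven stem-loop criteria

On the folded candidate window with the tag as the putative mature:

1. total base pairs ≥ 18;
2. largest unpaired run on one side within the stem ≤ 18 nt — the published
   wording ("errors in one bulge ≤ 18") is ambiguous between mismatches,
   asymmetry and bulge length; the largest single-side unpaired run is the
   one reading checkable on a structure, and the threshold is configurable;
3. MFE strictly below −20 kcal/mol ("under −20" read as strict; −20.0
   exactly fails);
4. ≥ 80% of mature bases are base-paired (an alternative "within the stem
   span including internal bulges" reading is available via
   `in_stem_mode="span"`);
5. hairpin length — the outermost-pair span (stems + terminal loop) —
   ≥ 53 nt;
6. terminal loop ≤ 22 nt;
7. mature A+U content in [30%, 70%], inclusive at both ends.

Candidate extraction follows the published filters: tags must be
unannotated, map to exactly one locus, and carry ≥ 5 reads (pooled over
both libraries, since the comparison pools tags before prediction). Two
windows per tag are excised — tag at the 5′ end with a 70 nt downstream
flank, and tag at the 3′ end with a 70 nt upstream flank, strand-aware and
clipped at chromosome ends — following the common excision convention for
this tool family. When both windows pass, the lower-MFE window is reported;
survivors are named `novel_miR_1..n` by descending total count.

## Differential expression

Normalization is transcripts per million clean reads, kept at full
precision internally and rounded to 4 decimals only in reports. Zeros
become 0.01 before comparison; miRNAs below 1 TPM in *both* libraries are
discarded. Fold change is log2(P/D) with strict gates (|log2fc| > 1).

The exact test conditions on the count in one library: given x among N₁,
the count among N₂ follows the Audic–Claverie distribution, equivalently a
negative binomial with x+1 successes and success probability 1/(1+N₂/N₁).
Everything is computed in log-gamma space; tails are summed term-by-term
until terms fall below a 10⁻¹² relative tolerance, and the larger tail is
obtained through the complement, so p-values of magnitude 10⁻¹⁰⁰⁰⁰⁰ remain
exact on the log10 scale. The default is the doubled smaller tail
(two-sided); the one-sided tail and the point probability are exposed
because published tables rarely state their convention — against the
published worked values the two-sided variant reproduces the strongest
finite row to two decimal places in log10 and the others within ~0.2.

Two caveats documented by tests rather than hidden: the *conditional* test
is only approximately invariant under swapping the libraries (the two
directions condition on different margins; the point probability is exactly
symmetric when N₁ = N₂, the tails shift by ≲ 0.5 in log10); and no
multiple-testing correction is applied, matching the workflow this package
implements. The label `**` means |log2fc| > 1 and p < 0.01, both strict.

## qPCR

Livak 2^−ΔΔCt with an assumed amplification efficiency of 2 for target and
reference (18S rRNA by default). Replicate ΔCt values are averaged on the
cycle scale before ΔΔCt — so the calibrator sample's fold is exactly 1 —
and the reported spread is the (n−1) standard deviation over per-replicate
folds. No efficiency correction or melt-curve QC.

## The synthetic study

The generator's defaults define the study conditions used by the tests and
the acceptance script: two libraries of 200,000 reads over a 100 kb toy
genome; 30 known miRNA hairpins, 10 novel hairpins, 10 decoys, 2 loci per
non-miRNA feature class; artifact fractions of roughly 0.5% low-quality,
0.2% adapter-null, 0.1% insert-null, 0.5% 5′-contaminant, 0.05% poly(A),
4% short (≈ 94.8% clean, matching the shape of real accounting tables);
clean reads split ~45% known miRNA, 5% novel, 5% decoy, 13.5% ncRNA
fragments, rest unannotated background; mature lengths peaked at 22 nt
(the canonical Dicer product); star reads at 5% of mature counts; and six
known miRNAs planted at log2 fold change ±2, applied symmetrically
(D × 2^−fc/2, P × 2^+fc/2) so class totals stay at their configured
fractions in both conditions.

Construction guarantees replace statistical hope wherever the tests need
exact truth. Hairpins are built, not sampled: 5 nt extension + mature +
8 nt loop + reverse complement of the 5′ arm, with three star-side pairs
broken by non-pairing substitutions — real mature/star duplexes are
imperfect, and without this every mature tag would map exactly to its own
star arm on the opposite strand and be discarded as a multi-mapper. Novel
hairpins are accepted only if at least one of their two actual excision
windows passes all seven criteria; decoys (cycling four designs: A+U-rich
mature violating c7, a 30 nt terminal loop violating c6, a loop-spanning
mature violating c4, and a stem-free random locus) only if both windows
fail overall *and* the named criterion fails in the hairpin-bearing window.
Every emitted insert is rejection-sampled against the classifier's own
rules, so each read classifies exactly as intended and the QC report equals
the manifest read for read. Artifact-class counts are multinomial over the
library total (a joint Poisson conditioned on the total), planted-locus
counts are Poisson around their condition means, and the background class
absorbs the remainder — so per-category counts sum to the library total
exactly. The same seed reproduces every byte.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: sequencing errors and quality-score
distributions; untemplated isomiR ends; genome-scale repeat structure and
multi-mapping ambiguity; ncRNA families that must be recognized by sequence
similarity; cross-species mapping divergence (the workflow this package
implements mapped goat reads to the bovine genome); and library-size
asymmetry beyond what the planted fold changes induce.

## Problem sizes

The shipped configuration is desk-scale by design: ~10⁵ reads per library
and a 10⁵ nt genome exercise every code path in minutes, and the package's
own accounting/recovery metrics are computed at that scale. Dataset-scale
published outcomes (total conserved/novel/differentially expressed counts)
are properties of a specific 1.5×10⁷-read dataset and are not reproduced;
the worked-example arithmetic on the published count tables is, exactly.

## Known limitations

Single-hairpin folding cannot score multibranch candidates (by design);
the mapper is exhaustive but not engineered for mammalian-genome scale;
annotation is positional only; conserved matching defaults to exact
sequence identity with end tolerance, so untemplated isomiRs are missed;
and the two-library test has no replicate model — it measures sampling
noise around pooled libraries, not biological variance.
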