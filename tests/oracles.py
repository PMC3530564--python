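"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's search strategies: the folding
oracle enumerates every nested-pair chain explicitly, and the mapping oracle
scans every genomic position with a vectorized Hamming comparison.
"""

from __future__ import annotations

import math

import numpy as np

from caprimir.fold import MAX_INTERIOR, MIN_LOOP, chain_energy, normalize_rna, pairable

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def enumerate_chains(seq: str):
    """Yield every admissible chain of nested pairs (outermost first)."""
    n = len(seq)
    starts = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_LOOP + 1, n)
        if pairable(seq[i], seq[j])
    ]

    def extend(chain):
        yield chain
        i, j = chain[-1]
        for i2 in range(i + 1, min(i + MAX_INTERIOR + 2, j)):
            for j2 in range(max(i2 + MIN_LOOP + 1, j - 1 - MAX_INTERIOR), j):
                if pairable(seq[i2], seq[j2]):
                    yield from extend(chain + [(i2, j2)])

    for p in starts:
        yield from extend([p])


def brute_force_mfe(sequence: str) -> tuple[float, int, str]:
    """Exhaustive minimum over all single-hairpin structures.

    Returns (mfe, n_pairs, dot_bracket) with the same tie-breaks as the DP:
    lower energy, then fewer pairs, then lexicographically smallest
    dot-bracket; the empty structure (energy 0) wins when nothing is
    negative.
    """
    seq = normalize_rna(sequence)
    best = (0.0, 0, "." * len(seq))
    for chain in enumerate_chains(seq):
        e = chain_energy(seq, chain)
        if e >= 0.0 or math.isinf(e):
            continue
        db = ["."] * len(seq)
        for i, j in chain:
            db[i], db[j] = "(", ")"
        cand = (e, len(chain), "".join(db))
        if cand < best:
            best = cand
    return best


def hamming_scan(genome: dict[str, str], tag: str, max_mismatch: int = 1):
    """All loci with Hamming distance <= max_mismatch, both strands.

    Returns sorted (chrom, start, strand, mismatches) tuples; vectorized
    sliding-window comparison over every position.
    """
    out = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for strand, query in (("+", tag), ("-", tag.translate(_COMPLEMENT)[::-1])):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            if len(arr) < len(q):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, len(q))
            mm = (windows != q).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                out.append((chrom, int(pos), strand, int(mm[pos])))
    return sorted(out)
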