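"""Minimum-free-energy folding of single-hairpin RNA secondary structures.

miRNA precursors fold into a single stem-loop, so the structure space here is
deliberately restricted to *chains* of nested base pairs: every pair contains
the next, there is one terminal loop and no multibranch loops.  This keeps the
dynamic program simple, makes exhaustive enumeration of the structure space
feasible at small lengths (the test oracle), and matches what the seven
stem-loop prediction criteria measure.

The energy model is a simplified nearest-neighbour scheme:

* Watson-Crick (A·U, G·C) and wobble (G·U) pairs.
* A 21-parameter stacking table (free energies in kcal/mol at 37 degC,
  expanded to all 36 ordered pair combinations by the usual reverse-complement
  symmetry).  Values follow the familiar published nearest-neighbour stacks
  for the Watson-Crick block and plausible figures for the wobble block.
* Logarithmic loop penalties for hairpin loops, bulges and internal loops,
  with an asymmetry term for internal loops.  No stacking across a bulge.
* Minimum hairpin loop of 3 nt; interior loops capped at ``MAX_INTERIOR``
  unpaired bases per side (loops larger than that are disallowed outright,
  both in the DP and in the enumeration oracle).

This is *not* a Turner/Mfold-parameter implementation: absolute energies of
real precursors are comparable in magnitude (a 20-bp stem lands well below
-20 kcal/mol) but are not expected to reproduce published Mfold values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "SecondaryStructure",
    "fold_mfe",
    "chain_energy",
    "hairpin_energy",
    "join_energy",
    "pairable",
    "normalize_rna",
    "MIN_LOOP",
    "MAX_INTERIOR",
]

MIN_LOOP = 3          # minimum unpaired bases in a terminal hairpin loop
MAX_INTERIOR = 30     # maximum unpaired run per side of a bulge/internal loop
_LOOP_COEF = 1.08     # ~1.75 RT at 37 degC, kcal/mol per natural-log unit

#: canonical stacking free energies, kcal/mol; key = (outer pair, inner pair)
#: written 5'->3' on the outer strand.  The remaining 15 ordered combinations
#: follow from the symmetry E(p, q) = E(rev q, rev p).
_CANONICAL_STACK = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("AU", "CG"): -2.24,
    ("AU", "GC"): -2.08,
    ("UA", "CG"): -2.35,
    ("UA", "GC"): -2.11,
    ("CG", "CG"): -3.26,
    ("CG", "GC"): -2.36,
    ("GC", "CG"): -3.42,
    ("AU", "GU"): -0.55,
    ("AU", "UG"): -1.36,
    ("UA", "GU"): -1.00,
    ("UA", "UG"): -1.27,
    ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11,
    ("GC", "GU"): -1.53,
    ("GC", "UG"): -2.51,
    ("GU", "GU"): -0.50,
    ("GU", "UG"): +1.29,
    ("UG", "GU"): -0.60,
}


def _revpair(p: str) -> str:
    return p[1] + p[0]


def _expand_stacks() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for (a, b), e in _CANONICAL_STACK.items():
        for key in ((a, b), (_revpair(b), _revpair(a))):
            if key in table and table[key] != e:
                raise AssertionError(f"inconsistent stack symmetry at {key}")
            table[key] = e
    assert len(table) == 36
    return table


STACK: dict[tuple[str, str], float] = _expand_stacks()

_PAIR_SET = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})


def pairable(a: str, b: str) -> bool:
    """True if nucleotides ``a`` and ``b`` can form a pair in this model."""
    return a + b in _PAIR_SET


def normalize_rna(sequence: str) -> str:
    """Uppercase, T->U; raises on characters outside ACGU(T)."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGUT characters in sequence: {sorted(bad)}")
    return seq


def hairpin_energy(loop_len: int) -> float:
    """Penalty for closing a terminal loop of ``loop_len`` unpaired bases."""
    if loop_len < MIN_LOOP:
        return math.inf
    return 5.0 + _LOOP_COEF * math.log(loop_len / MIN_LOOP)


def _bulge_energy(length: int) -> float:
    return 3.8 + _LOOP_COEF * math.log(length)


def _internal_energy(l5: int, l3: int) -> float:
    return 2.0 + _LOOP_COEF * math.log((l5 + l3) / 2.0) + 0.55 * abs(l5 - l3)


def join_energy(seq: str, i: int, j: int, i2: int, j2: int) -> float:
    """Energy of placing pair (i2, j2) directly inside pair (i, j).

    Adjacent pairs stack; otherwise a bulge or internal-loop penalty applies
    (no stacking bonus across the loop).  Loops with more than
    ``MAX_INTERIOR`` unpaired bases on either side are disallowed.
    """
    l5 = i2 - i - 1
    l3 = j - j2 - 1
    if l5 < 0 or l3 < 0:
        raise ValueError("inner pair must nest strictly inside the outer pair")
    if l5 == 0 and l3 == 0:
        return STACK[(seq[i] + seq[j], seq[i2] + seq[j2])]
    if l5 > MAX_INTERIOR or l3 > MAX_INTERIOR:
        return math.inf
    if l5 == 0 or l3 == 0:
        return _bulge_energy(l5 + l3)
    return _internal_energy(l5, l3)


def chain_energy(sequence: str, chain: list[tuple[int, int]]) -> float:
    """Free energy of an explicit chain of nested pairs (outermost first).

    The empty chain has energy 0.  Used by the simulator's construction checks
    and by the exhaustive test oracle.
    """
    seq = normalize_rna(sequence)
    if not chain:
        return 0.0
    e = 0.0
    for (i, j), (i2, j2) in zip(chain, chain[1:]):
        e += join_energy(seq, i, j, i2, j2)
    ii, jj = chain[-1]
    e += hairpin_energy(jj - ii - 1)
    for i, j in chain:
        if not pairable(seq[i], seq[j]):
            return math.inf
    return e


@dataclass(frozen=True)
class SecondaryStructure:
    """A predicted structure: dot-bracket string plus its free energy.

    ``pairs`` lists the base pairs outermost-first; ``mfe`` is 0.0 exactly
    when no pair is predicted.
    """

    sequence: str
    dot_bracket: str
    mfe: float
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.sequence):
            raise ValueError("dot-bracket length mismatch")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def fold_mfe(sequence: str, min_length: int = 10) -> SecondaryStructure:
    """Fold ``sequence`` into its minimum-free-energy single hairpin.

    Dynamic program over candidate outermost pairs: ``E(i, j)`` is the best
    energy of a chain whose outermost pair is (i, j), computed from smaller
    spans inward.  Ties are broken toward fewer pairs, then toward the
    lexicographically smallest dot-bracket string, deterministically.

    Parameters
    ----------
    sequence:
        RNA or DNA string (T is read as U), length >= ``min_length``.

    Returns
    -------
    SecondaryStructure
        The optimal structure; an all-unpaired structure with ``mfe == 0.0``
        if no chain achieves negative free energy.
    """
    seq = normalize_rna(sequence)
    n = len(seq)
    if n < min_length:
        raise ValueError(f"sequence shorter than {min_length} nt")

    partners: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        ai = seq[i]
        for j in range(i + MIN_LOOP + 1, n):
            if pairable(ai, seq[j]):
                partners[i].append(j)

    energy: dict[tuple[int, int], float] = {}
    npairs: dict[tuple[int, int], int] = {}
    segdb: dict[tuple[int, int], str] = {}

    def candidate_db(i: int, j: int, choice: Optional[tuple[int, int]]) -> str:
        if choice is None:
            return "(" + "." * (j - i - 1) + ")"
        i2, j2 = choice
        return "(" + "." * (i2 - i - 1) + segdb[(i2, j2)] + "." * (j - j2 - 1) + ")"

    # states in order of increasing span so inner states are always ready
    states = sorted(
        ((i, j) for i in range(n) for j in partners[i]), key=lambda p: p[1] - p[0]
    )
    import bisect

    for i, j in states:
        best_e = hairpin_energy(j - i - 1)
        best_np = 1
        best_choice: Optional[tuple[int, int]] = None
        pair_ij = seq[i] + seq[j]
        lo_j2 = max(i + MIN_LOOP + 2, j - 1 - MAX_INTERIOR)
        for i2 in range(i + 1, min(i + MAX_INTERIOR + 2, j - MIN_LOOP - 1)):
            plist = partners[i2]
            a = bisect.bisect_left(plist, lo_j2)
            l5 = i2 - i - 1
            for idx in range(a, len(plist)):
                j2 = plist[idx]
                if j2 >= j:
                    break
                l3 = j - j2 - 1
                if l5 == 0 and l3 == 0:
                    e_join = STACK[(pair_ij, seq[i2] + seq[j2])]
                elif l5 == 0 or l3 == 0:
                    e_join = _bulge_energy(l5 + l3)
                else:
                    e_join = _internal_energy(l5, l3)
                e = e_join + energy[(i2, j2)]
                np_ = npairs[(i2, j2)] + 1
                if e < best_e or (
                    e == best_e
                    and (
                        np_ < best_np
                        or (
                            np_ == best_np
                            and candidate_db(i, j, (i2, j2))
                            < candidate_db(i, j, best_choice)
                        )
                    )
                ):
                    best_e, best_np, best_choice = e, np_, (i2, j2)
        energy[(i, j)] = best_e
        npairs[(i, j)] = best_np
        segdb[(i, j)] = candidate_db(i, j, best_choice)

    best_key: Optional[tuple[int, int]] = None
    best = (0.0, 0, "." * n)  # the empty structure
    for i, j in states:
        e = energy[(i, j)]
        if e >= 0.0:
            continue
        db = "." * i + segdb[(i, j)] + "." * (n - j - 1)
        cand = (e, npairs[(i, j)], db)
        if cand < best:
            best = cand
            best_key = (i, j)

    e, _, db = best
    pairs: list[tuple[int, int]] = []
    if best_key is not None:
        stack: list[int] = []
        for pos, ch in enumerate(db):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                pairs.append((stack.pop(), pos))
        pairs.sort()
    return SecondaryStructure(sequence=seq, dot_bracket=db, mfe=float(e), pairs=tuple(pairs))
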