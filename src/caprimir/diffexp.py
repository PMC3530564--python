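"""Two-library miRNA differential expression.

Expression in each library is normalized to transcripts per million clean
reads; zeros are replaced by 0.01 before comparison and miRNAs below one
transcript per million in *both* libraries are discarded.  Significance of a
count difference between the two (unreplicated) libraries uses the
Audic-Claverie exact test: conditioned on observing ``x`` reads among ``N1``
in one library, the count ``y`` among ``N2`` in the other follows

    p(k | x) = r^k * (x+k)! / (x! k!) * (1+r)^-(x+k+1),    r = N2/N1,

a negative-binomial distribution with ``x+1`` successes and success
probability ``1/(1+r)``.  Tail sums are evaluated in log-gamma space so that
p-values far below double-precision underflow remain exact on the log10
scale.  The default is the doubled smaller tail (two-sided); the one-sided
tail and the point probability are exposed for reconciliation with published
tables.  An miRNA is labelled ``**`` when |log2 fold change| > 1 and
p < 0.01 (strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "ExpressionRecord",
    "normalize",
    "adjust_and_filter",
    "fold_change",
    "ac_pvalue",
    "ac_log10_pvalue",
    "sig_label",
    "diff_table",
    "format_pvalue",
]

Variant = Literal["two-sided", "one-sided", "point"]

ZERO_SUBSTITUTE = 0.01
EXPRESSION_FLOOR = 1.0
FC_GATE = 1.0
P_GATE = 0.01
_LN10 = math.log(10.0)
_REL_TOL_LOG = math.log(1e-12)


def normalize(count: float, total: int) -> float:
    """Transcripts per million clean reads: count / total * 1e6, exact."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total * 1_000_000.0


def adjust_and_filter(x_norm: float, y_norm: float) -> tuple[float, float, bool]:
    """Apply the zero-substitution and low-expression discard rules.

    Returns (X', Y', filtered): zeros become 0.01; ``filtered`` is True when
    both adjusted values are below one transcript per million.
    """
    if x_norm < 0 or y_norm < 0:
        raise ValueError("normalized expressions must be non-negative")
    x_adj = ZERO_SUBSTITUTE if x_norm == 0 else x_norm
    y_adj = ZERO_SUBSTITUTE if y_norm == 0 else y_norm
    filtered = x_adj < EXPRESSION_FLOOR and y_adj < EXPRESSION_FLOOR
    return x_adj, y_adj, filtered


def fold_change(x_adj: float, y_adj: float) -> float:
    """log2(Y'/X'), peak over dry by convention."""
    if x_adj <= 0 or y_adj <= 0:
        raise ValueError("adjusted expressions must be positive")
    return math.log2(y_adj / x_adj)


def _log_pmf(ks: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        ks * log_r
        + gammaln(x + ks + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ks + 1.0)
        - (x + ks + 1.0) * log_1pr
    )


def _log_min_tail(x: int, y: int, n1: int, n2: int) -> tuple[float, float]:
    """(log lower tail P(K<=y), log upper tail P(K>=y)), smaller one summed
    directly term-by-term; terms are accumulated until they fall below a
    1e-12 relative tolerance."""
    r = n2 / n1
    log_r = math.log(r)
    log_1pr = math.log1p(r)
    mean = (x + 1) * r  # mean of the conditional distribution
    if y <= mean:
        ks = np.arange(0, y + 1, dtype=float)
        lower = float(logsumexp(_log_pmf(ks, x, log_r, log_1pr)))
        upper = _log_complement_tail(x, y, log_r, log_1pr, side="upper")
    else:
        upper = _log_open_upper(x, y, log_r, log_1pr)
        lower = _log_complement_tail(x, y, log_r, log_1pr, side="lower")
    return lower, upper


def _log_open_upper(x: int, y: int, log_r: float, log_1pr: float) -> float:
    """log P(K >= y) summed upward from y until relative underflow."""
    chunks = []
    running = -math.inf
    k0 = y
    while True:
        ks = np.arange(k0, k0 + 4096, dtype=float)
        lp = _log_pmf(ks, x, log_r, log_1pr)
        chunks.append(lp)
        running = float(logsumexp(np.concatenate(chunks)))
        if lp[-1] < running + _REL_TOL_LOG:
            return running
        k0 += 4096


def _log_complement_tail(x: int, y: int, log_r: float, log_1pr: float, side: str) -> float:
    """log of the larger tail via its complement (safe: it is near 1)."""
    if side == "upper":
        # P(K >= y) = 1 - P(K <= y-1)
        if y == 0:
            return 0.0
        ks = np.arange(0, y, dtype=float)
        log_cdf = float(logsumexp(_log_pmf(ks, x, log_r, log_1pr)))
    else:
        # P(K <= y) = 1 - P(K >= y+1)
        log_cdf = _log_open_upper(x, y + 1, log_r, log_1pr)
    if log_cdf >= 0.0:
        return -math.inf
    return math.log(-math.expm1(log_cdf))


def ac_log10_pvalue(
    x: int, y: int, n1: int, n2: int, variant: Variant = "two-sided"
) -> float:
    """log10 of the Audic-Claverie p-value (never underflows)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if variant == "point":
        r = n2 / n1
        lp = float(_log_pmf(np.array([float(y)]), x, math.log(r), math.log1p(r))[0])
        return lp / _LN10
    lower, upper = _log_min_tail(x, y, n1, n2)
    log_min = min(lower, upper)
    if variant == "one-sided":
        return min(0.0, log_min) / _LN10
    if variant == "two-sided":
        return min(0.0, log_min + math.log(2.0)) / _LN10
    raise ValueError(f"unknown variant {variant!r}")


def ac_pvalue(x: int, y: int, n1: int, n2: int, variant: Variant = "two-sided") -> float:
    """Audic-Claverie p-value as a float (0.0 on double underflow).

    ``variant`` selects the two-sided doubled-tail (default), the one-sided
    smaller tail, or the point probability p(y | x).
    """
    return 10.0 ** ac_log10_pvalue(x, y, n1, n2, variant)


def sig_label(log2fc: float, pvalue: float) -> str:
    """Significance label: '**' iff |log2fc| > 1 and p < 0.01 (strict)."""
    if not (math.isfinite(log2fc) and math.isfinite(pvalue)):
        raise ValueError("inputs must be finite")
    return "**" if (log2fc > FC_GATE or log2fc < -FC_GATE) and pvalue < P_GATE else ""


def format_pvalue(log10p: float) -> str:
    """Scientific-notation string on the published scale; '0' below 1e-320."""
    if log10p < -320:
        return "0"
    mantissa = 10 ** (log10p - math.floor(log10p))
    return f"{mantissa:.2f}E{int(math.floor(log10p))}"


@dataclass
class ExpressionRecord:
    """One miRNA's worth of the two-library comparison (a report row)."""

    name: str
    x: int
    y: int
    n1: int
    n2: int
    x_norm: float
    y_norm: float
    x_adj: float
    y_adj: float
    log2fc: float
    pvalue: float
    log10_pvalue: float
    label: str
    filtered: bool


def diff_table(
    counts_d: Mapping[str, int],
    counts_p: Mapping[str, int],
    n1: int,
    n2: int,
    variant: Variant = "two-sided",
) -> tuple[list[ExpressionRecord], dict]:
    """Full comparison over the union of miRNA names (missing count = 0).

    Returns the records (sorted by name) and a summary counting up- and
    down-regulated miRNAs at the '**' threshold among unfiltered records.
    """
    names = sorted(set(counts_d) | set(counts_p))
    records = []
    up = down = 0
    for name in names:
        x = int(counts_d.get(name, 0))
        y = int(counts_p.get(name, 0))
        x_norm = normalize(x, n1)
        y_norm = normalize(y, n2)
        x_adj, y_adj, filtered = adjust_and_filter(x_norm, y_norm)
        fc = fold_change(x_adj, y_adj)
        log10p = ac_log10_pvalue(x, y, n1, n2, variant)
        p = 10.0 ** log10p
        label = sig_label(fc, p)
        if not filtered and label:
            if fc > 0:
                up += 1
            else:
                down += 1
        records.append(
            ExpressionRecord(name, x, y, n1, n2, x_norm, y_norm, x_adj, y_adj,
                             fc, p, log10p, label, filtered)
        )
    summary = {
        "tested": sum(1 for r in records if not r.filtered),
        "filtered": sum(1 for r in records if r.filtered),
        "up": up,
        "down": down,
        "significant": up + down,
    }
    return records, summary


def diff_table_frame(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    """Report-shaped DataFrame (counts, normalized values, fold change,
    p-value string, label), 4-decimal rounding as in the published table."""
    rows = []
    for r in records:
        rows.append(
            {
                "miRNA": r.name,
                "D": r.x,
                "P": r.y,
                "D-NE": round(r.x_norm, 4),
                "P-NE": round(r.y_norm, 4),
                "log2fc": round(r.log2fc, 4),
                "P-value": format_pvalue(r.log10_pvalue),
                "sig": r.label,
                "filtered": r.filtered,
            }
        )
    return pd.DataFrame(
        rows, columns=["miRNA", "D", "P", "D-NE", "P-NE", "log2fc", "P-value", "sig", "filtered"]
    )
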