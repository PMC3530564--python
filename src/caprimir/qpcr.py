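"""Relative miRNA quantification from stem-loop qRT-PCR Ct values.

Livak 2^-ddCt method: each sample's target Ct is normalized to a reference
gene (18S rRNA by default), replicate dCt values are averaged on the cycle
scale, and expression is reported relative to a calibrator sample.  Assumes
amplification efficiency 2 for both target and reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CtMeasurement",
    "RelativeExpression",
    "delta_delta_ct",
    "relative_expression",
    "summarize_replicates",
    "analyze_ct_table",
]

DEFAULT_REFERENCE = "18S rRNA"


@dataclass(frozen=True)
class CtMeasurement:
    """One well: target and reference Ct cycles for a sample replicate."""

    sample: str
    target: str
    ct_target: float
    ct_reference: float
    reference: str = DEFAULT_REFERENCE
    replicate: int = 1

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("Ct values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class RelativeExpression:
    sample: str
    target: str
    fold: float
    sd: float


def delta_delta_ct(sample: CtMeasurement, calibrator: CtMeasurement) -> float:
    """ddCt = dCt(sample) - dCt(calibrator); same target and reference gene."""
    if sample.target != calibrator.target or sample.reference != calibrator.reference:
        raise ValueError("sample and calibrator must share target and reference genes")
    return sample.delta_ct - calibrator.delta_ct


def relative_expression(ddct: float) -> float:
    """Fold change 2^-ddCt."""
    if not math.isfinite(ddct):
        raise ValueError("ddCt must be finite")
    return 2.0 ** (-ddct)


def summarize_replicates(folds: Sequence[float]) -> tuple[float, float]:
    """Sample mean and (n-1) standard deviation over >= 2 replicate folds."""
    if len(folds) < 2:
        raise ValueError("at least two replicates required")
    return mean(folds), stdev(folds)


def analyze_ct_table(
    measurements: Iterable[CtMeasurement], calibrator_sample: str
) -> pd.DataFrame:
    """Per-(sample, target) relative expression against a calibrator sample.

    Replicate dCt values are averaged on the cycle scale before ddCt (so the
    calibrator's mean fold is exactly 1); the reported sd is over the
    per-replicate folds.
    """
    ms = list(measurements)
    by_key: dict[tuple[str, str], list[CtMeasurement]] = {}
    for m in ms:
        by_key.setdefault((m.sample, m.target), []).append(m)
    targets = {t for (_s, t) in by_key}
    rows = []
    for target in sorted(targets):
        cal = by_key.get((calibrator_sample, target))
        if not cal:
            raise ValueError(f"calibrator sample {calibrator_sample!r} missing for {target!r}")
        cal_dct = mean(m.delta_ct for m in cal)
        for (sample, t), group in sorted(by_key.items()):
            if t != target:
                continue
            mean_dct = mean(m.delta_ct for m in group)
            fold = relative_expression(mean_dct - cal_dct)
            rep_folds = [relative_expression(m.delta_ct - cal_dct) for m in group]
            sd = stdev(rep_folds) if len(rep_folds) >= 2 else 0.0
            rows.append(
                {"sample": sample, "target": target, "fold": fold, "sd": sd,
                 "n_replicates": len(group)}
            )
    return pd.DataFrame(rows, columns=["sample", "target", "fold", "sd", "n_replicates"])
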