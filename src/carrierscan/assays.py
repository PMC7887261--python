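"""Functional-validation arithmetic: qPCR relative expression and the
flow-cytometry DNA-damage ratio."""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Sequence


@dataclass(frozen=True)
class CtMeasurements:
    """Replicate qPCR cycle thresholds for a target and a housekeeping gene
    under a treated and a control condition."""

    target_treated: Sequence[float]
    target_control: Sequence[float]
    housekeeping_treated: Sequence[float]
    housekeeping_control: Sequence[float]

    def __post_init__(self) -> None:
        for name in (
            "target_treated",
            "target_control",
            "housekeeping_treated",
            "housekeeping_control",
        ):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name}: at least one replicate required")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name}: Ct values must be positive")


def ddct_fold_change(m: CtMeasurements) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = mean(target Ct) - mean(housekeeping Ct) per condition;
    ddCt = dCt(treated) - dCt(control); returns 2^-ddCt.
    Replicates are aggregated by arithmetic mean of Ct.
    """
    dct_treated = fmean(m.target_treated) - fmean(m.housekeeping_treated)
    dct_control = fmean(m.target_control) - fmean(m.housekeeping_control)
    return 2.0 ** -(dct_treated - dct_control)


@dataclass(frozen=True)
class QuadrantCounts:
    """Flow-cytometry quadrant counts: Q1 untransfected damage-positive,
    Q2 transfected damage-positive, Q3 transfected damage-negative,
    Q4 untransfected damage-negative."""

    q1: int
    q2: int
    q3: int
    q4: int

    def __post_init__(self) -> None:
        if min(self.q1, self.q2, self.q3, self.q4) < 0:
            raise ValueError("quadrant counts must be non-negative")


def damage_ratio(q: QuadrantCounts) -> float:
    """DNA-damage ratio (Q2/Q3)/(Q1/Q4): transfected damage-positive odds
    normalized by the untransfected background odds."""
    if q.q1 == 0 or q.q3 == 0 or q.q4 == 0:
        raise ValueError("damage ratio undefined when Q1, Q3 or Q4 is zero")
    return (q.q2 / q.q3) / (q.q1 / q.q4)
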