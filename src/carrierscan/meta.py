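"""Sparse-count inverse-variance fixed-effects meta-analysis of carrier
2x2 tables.

Rare-variant validation strata are extremely sparse: whole cohorts can have
zero carriers in one arm.  Each stratum's log odds ratio and variance are
therefore computed with the Haldane-Anscombe correction -- 0.5 added to all
four cells of any stratum containing a zero cell, per stratum only -- and
0/0-carrier strata are retained rather than dropped, so they contribute a
near-null, heavily down-weighted effect instead of silently vanishing.
Pooling is standard fixed-effects: weights 1/var(lnOR), Wald CI with
z = 1.959964, Cochran's Q and I^2 for heterogeneity.

By default the meta-analysis pools the sequencing strata (discovery
case/control pair, familial cases vs normal-lung-function controls, tumor
atlas cases vs reference-population controls); genotyping-array strata are
included only on request via ``include_array_strata``.  Aggregate carrier
frequencies, in contrast, always sum the uncorrected counts of every
supplied stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import erfc, sqrt

import numpy as np
import pandas as pd

from .assoc import Z95, CarrierTable, bh_fdr


@dataclass(frozen=True)
class Stratum2x2:
    label: str
    table: CarrierTable
    corrected: bool
    log_or: float
    var_log_or: float

    @property
    def weight(self) -> float:
        return 1.0 / self.var_log_or


@dataclass(frozen=True)
class MetaResult:
    pooled_log_or: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q_het: float
    i2: float
    n_strata: int
    case_freq: float
    control_freq: float
    contributions: tuple[tuple[str, float], ...]  # (label, normalized weight)


def stratum_log_or(table: CarrierTable, label: str = "") -> Stratum2x2:
    """Per-stratum log OR and variance with the all-cell 0.5 correction
    applied iff the stratum contains a zero cell."""
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("both margins of the stratum must be positive")
    a, b, c, d = table.corrected_cells()
    log_or = float(np.log((a * d) / (b * c)))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return Stratum2x2(
        label=label,
        table=table,
        corrected=table.has_zero_cell,
        log_or=log_or,
        var_log_or=float(var),
    )


def _norm_sf2(z: float) -> float:
    """Two-sided normal tail via the complementary error function."""
    return erfc(abs(z) / sqrt(2.0))


def ivw_meta(strata: list[Stratum2x2]) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling of stratum log-ORs."""
    if not strata:
        raise ValueError("no strata supplied")
    lors = np.array([s.log_or for s in strata])
    w = np.array([s.weight for s in strata])
    pooled = float((w * lors).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = pooled / se
    p = _norm_sf2(z)
    q = float((w * (lors - pooled) ** 2).sum())
    df = len(strata) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    case_freq, control_freq = aggregate_freq(strata)
    return MetaResult(
        pooled_log_or=pooled,
        se=se,
        or_point=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - Z95 * se)),
        ci_high=float(np.exp(pooled + Z95 * se)),
        z=float(z),
        p=float(p),
        q_het=q,
        i2=float(i2),
        n_strata=len(strata),
        case_freq=case_freq,
        control_freq=control_freq,
        contributions=tuple((s.label, float(wi)) for s, wi in zip(strata, w / w.sum())),
    )


def aggregate_freq(strata: list[Stratum2x2]) -> tuple[float, float]:
    """Aggregate carrier percentages over the *uncorrected* counts of all
    supplied strata: 100 * sum(a) / sum(cases), 100 * sum(c) / sum(controls)."""
    if not strata:
        raise ValueError("no strata supplied")
    cases = sum(s.table.n_cases for s in strata)
    controls = sum(s.table.n_controls for s in strata)
    if cases == 0 or controls == 0:
        raise ValueError("zero case or control denominator")
    a = sum(s.table.a for s in strata)
    c = sum(s.table.c for s in strata)
    return 100.0 * a / cases, 100.0 * c / controls


# ---------------------------------------------------------------------------
# packaged printed carrier counts (validated candidates)
# ---------------------------------------------------------------------------

def printed_strata_table() -> pd.DataFrame:
    """The packaged per-cohort carrier counts for the five validated
    candidate variants (columns: candidate, stratum, platform, a, n_cases,
    c, n_controls)."""
    with resources.files("carrierscan.data").joinpath("validated_strata.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_printed_strata(
    candidate: str, include_array_strata: bool = False
) -> list[Stratum2x2]:
    """Strata for one validated candidate gene (e.g. ``"ATM"``).

    ``include_array_strata=False`` (default) restricts to the sequencing
    cohort pairs, which is the stratum set under which the pooled estimates
    for all five candidates are mutually consistent.
    """
    df = printed_strata_table()
    rows = df[df["candidate"] == candidate]
    if rows.empty:
        raise KeyError(f"unknown candidate {candidate!r}")
    if not include_array_strata:
        rows = rows[rows["platform"] == "sequencing"]
    return [
        stratum_log_or(
            CarrierTable(
                int(r.a), int(r.n_cases) - int(r.a), int(r.c), int(r.n_controls) - int(r.c)
            ),
            label=str(r.stratum),
        )
        for r in rows.itertuples()
    ]


def meta_validated_candidates(include_array_strata: bool = False) -> pd.DataFrame:
    """Pooled fixed-effects results for all packaged candidates, with
    aggregate frequencies computed over *all* printed strata (matching how
    the per-candidate totals are tabulated) and BH-FDR across candidates."""
    df = printed_strata_table()
    rows = []
    for cand in df["candidate"].unique():
        strata = load_printed_strata(cand, include_array_strata=include_array_strata)
        all_strata = load_printed_strata(cand, include_array_strata=True)
        res = ivw_meta(strata)
        case_freq, control_freq = aggregate_freq(all_strata)
        rows.append(
            {
                "candidate": cand,
                "n_strata": res.n_strata,
                "case_freq_pct": case_freq,
                "control_freq_pct": control_freq,
                "or": res.or_point,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "q_het": res.q_het,
                "i2": res.i2,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].tolist())
    return out
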