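"""Carrier-based single-variant association and gene-environment analysis.

All single-variant tests operate on carrier counts (dominant coding:
genotype >= 1) in a 2x2 table.  The exact test sums hypergeometric
probabilities no larger than the observed table's; odds ratios on tables
containing a zero use the Haldane-Anscombe correction (0.5 added to all
four cells), the same rule the meta-analysis module applies per stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CohortDataset, exposure_values

Z95 = 1.959964  #: normal quantile for 95% Wald intervals


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier counts: a/b = case carriers/non-carriers, c/d = control
    carriers/non-carriers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("carrier counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def has_zero_cell(self) -> bool:
        return 0 in self.cells

    def corrected_cells(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe: add 0.5 to every cell if any cell is zero."""
        if self.has_zero_cell:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return tuple(float(x) for x in self.cells)

    def swapped(self) -> "CarrierTable":
        """Swap the case and control rows (maps OR to 1/OR)."""
        return CarrierTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssocResult:
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    q: float = float("nan")
    direction: str = "null"


def carrier_counts(dataset: CohortDataset, variant: str | int) -> CarrierTable:
    """Tabulate carriers for one variant; samples with a missing call at
    that variant are excluded from its table."""
    j = dataset.variant_index(variant)
    g = dataset.genotypes[:, j]
    called = g != -1
    carrier = g >= 1
    case = dataset.case_mask
    a = int((carrier & case & called).sum())
    b = int((~carrier & case & called).sum())
    c = int((carrier & ~case & called).sum())
    d = int((~carrier & ~case & called).sum())
    return CarrierTable(a, b, c, d)


def fisher_assoc(table: CarrierTable) -> AssocResult:
    """Two-sided Fisher exact test with Haldane-corrected OR and Wald CI.

    The p-value sums hypergeometric probabilities <= the observed table's
    probability (probability-mass two-sided convention).  The OR and its
    95% CI, exp(ln OR +/- 1.96 sqrt(sum 1/cell)), are computed on the
    corrected cells whenever the table contains a zero.
    """
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("both case and control margins must be positive")
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    a, b, c, d = table.corrected_cells()
    or_point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(or_point) - Z95 * se))
    ci_high = float(np.exp(np.log(or_point) + Z95 * se))
    direction = "risk" if or_point > 1 else ("protective" if or_point < 1 else "null")
    return AssocResult(
        or_point=float(or_point),
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(p),
        direction=direction,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# dose-effect (joint allele) analysis
# ---------------------------------------------------------------------------

@dataclass
class DoseEffectResult:
    """Counts per (risk, protective) allele-count group and a
    Cochran-Armitage trend test over risk-allele count (computed among
    samples carrying no protective allele, so the zero group is a clean
    baseline)."""

    groups: pd.DataFrame  # columns: n_risk, n_protective, n_case, n_control
    trend_z: float
    trend_p: float


def _cochran_armitage(scores: np.ndarray, n_case: np.ndarray, n_control: np.ndarray):
    n = n_case + n_control
    N = n.sum()
    N1 = n_case.sum()
    N0 = n_control.sum()
    if N1 == 0 or N0 == 0 or N < 2:
        return float("nan"), float("nan")
    u = float((scores * (n_case - n * N1 / N)).sum())
    var = (N1 * N0 / (N * (N - 1))) * float(
        (n * scores**2).sum() - (n * scores).sum() ** 2 / N
    )
    if var <= 0:
        return float("nan"), float("nan")
    z = u / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def dose_effect_groups(
    dataset: CohortDataset,
    risk_set: Sequence[str | int],
    protective_set: Sequence[str | int],
) -> DoseEffectResult:
    """Assign each sample its (risk, protective) carried-variant counts and
    test for a risk trend.  A variant counts once per sample regardless of
    zygosity (carrier coding); missing calls count as non-carried."""
    risk_idx = [dataset.variant_index(v) for v in risk_set]
    prot_idx = [dataset.variant_index(v) for v in protective_set]
    if set(risk_idx) & set(prot_idx):
        raise ValueError("risk and protective variant sets overlap")

    geno = dataset.genotypes
    n_risk = (geno[:, risk_idx] >= 1).sum(axis=1) if risk_idx else np.zeros(len(geno), int)
    n_prot = (geno[:, prot_idx] >= 1).sum(axis=1) if prot_idx else np.zeros(len(geno), int)
    case = dataset.case_mask

    df = (
        pd.DataFrame(
            {"n_risk": n_risk, "n_protective": n_prot, "case": case.astype(int)}
        )
        .groupby(["n_risk", "n_protective"])["case"]
        .agg(n_case="sum", n_control=lambda s: int((1 - s).sum()))
        .reset_index()
        .sort_values(["n_risk", "n_protective"], ignore_index=True)
    )

    baseline = n_prot == 0
    trend = (
        pd.DataFrame({"r": n_risk[baseline], "case": case[baseline].astype(int)})
        .groupby("r")["case"]
        .agg(n_case="sum", n="count")
        .reset_index()
    )
    z, p = _cochran_armitage(
        trend["r"].to_numpy(float),
        trend["n_case"].to_numpy(float),
        (trend["n"] - trend["n_case"]).to_numpy(float),
    )
    return DoseEffectResult(groups=df, trend_z=z, trend_p=p)


# ---------------------------------------------------------------------------
# gene-environment interaction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GxEResult:
    coef: float
    se: float
    p: float
    method: str  # 'logistic' or 'exact'
    separation: bool = False

    @property
    def or_interaction(self) -> float:
        return float(np.exp(self.coef))


def carrier_composition_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided exact p for a 2x2 carrier-composition table (e.g. exposure
    by phenotype among carriers), by hypergeometric probability summation."""
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def gxe_interaction(
    dataset: CohortDataset,
    variant: str | int,
    exposure: str,
    adjust: Sequence[str] = (),
) -> GxEResult:
    """Carrier-by-exposure interaction on disease status.

    Fits a maximum-likelihood logistic regression
    ``phenotype ~ carrier + exposure + carrier:exposure + adjust`` and
    returns the interaction coefficient with its Wald SE and p.  When the
    fit degenerates (perfect separation, non-convergence, or an empty
    carrier-by-exposure cell) the method falls back to a stratified exact
    comparison -- a two-sided exact test of exposure composition within
    carriers by phenotype -- and records which method was used.  Complete
    separation is reported as a flagged result, never an exception.
    """
    j = dataset.variant_index(variant)
    g = dataset.genotypes[:, j]
    called = g != -1
    carrier = (g >= 1).astype(float)
    expo = exposure_values(dataset.samples, exposure)
    y = dataset.samples["phenotype"].to_numpy(dtype=float)

    cols = {"carrier": carrier, "exposure": expo, "interaction": carrier * expo}
    for name in adjust:
        cols[name] = exposure_values(dataset.samples, name)
    X = pd.DataFrame(cols)
    keep = called & np.isfinite(X.to_numpy(float)).all(axis=1)
    X = sm.add_constant(X.loc[keep], has_constant="add")
    yk = y[keep]

    if np.var(carrier[keep]) == 0:
        raise ValueError("carrier status has zero variance")

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yk, X).fit(disp=0, maxiter=200)
            coef = float(fit.params["interaction"])
            se = float(fit.bse["interaction"])
            converged = bool(fit.mle_retvals.get("converged", False))
            if converged and np.isfinite(coef) and np.isfinite(se) and abs(coef) < 50 and se < 50:
                result = GxEResult(
                    coef=coef, se=se, p=float(fit.pvalues["interaction"]), method="logistic"
                )
        except Exception:
            result = None

    if result is not None:
        return result

    # degenerate fit: exact comparison of exposure within carriers by phenotype
    is_carrier = (carrier >= 1) & keep
    expo_bin = expo > 0
    case = dataset.samples["phenotype"].to_numpy() == 1
    t = [
        [int((is_carrier & case & expo_bin).sum()), int((is_carrier & case & ~expo_bin).sum())],
        [int((is_carrier & ~case & expo_bin).sum()), int((is_carrier & ~case & ~expo_bin).sum())],
    ]
    p = carrier_composition_exact(t)
    return GxEResult(coef=float("nan"), se=float("nan"), p=p, method="exact", separation=True)
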