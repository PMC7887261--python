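"""Gene-level collapsing tests: CMC carrier collapse and the KBAC
multi-marker-genotype kernel test.

KBAC enumerates the distinct non-reference genotype vectors ("multi-marker
genotype patterns") over a gene's qualifying variants.  Each pattern i with
n_i carriers, of whom n_i^A are cases, receives a hypergeometric-kernel
weight

    w_i = P(X <= n_i^A),   X ~ Hypergeometric(N, n_cases, n_i),

i.e. the null probability of seeing at most the observed case enrichment,
and the statistic is the weighted difference of pattern frequencies

    S = sum_i w_i * (n_i^A / n_cases - n_i^U / n_controls).

Significance is one-sided (risk direction) by case/control label
permutation with the weights recomputed under each permuted labeling.
Because patterns partition the samples, a label permutation is equivalent
to a multivariate-hypergeometric draw of per-pattern case counts, which is
how permutations are sampled here (exactly, not approximately).

CMC collapses the gene to a binary carries-any-qualifying-variant indicator
and applies the exact carrier test; an adjusted logistic estimate is
reported alongside when covariates are requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import CarrierTable, bh_fdr, fisher_assoc
from .types import MISSING, CohortDataset, exposure_values


@dataclass(frozen=True)
class GenotypePattern:
    """One distinct non-reference multi-site genotype vector."""

    pattern_key: tuple[int, ...]
    n_total: int
    n_case: int
    n_control: int
    weight: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_case + self.n_control != self.n_total:
            raise ValueError("pattern counts must satisfy n_case + n_control = n_total")
        if all(g == 0 for g in self.pattern_key):
            raise ValueError("the all-reference pattern is excluded from scoring")


@dataclass
class BurdenResult:
    gene: str
    n_variants: int
    n_patterns: int
    carriers_case: int
    carriers_control: int
    kbac_stat: float
    kbac_p: float
    cmc_or: float
    cmc_ci: tuple[float, float]
    cmc_p: float
    cmc_or_adjusted: float | None = None
    degenerate: bool = False
    q_kbac: float = float("nan")
    q_cmc: float = float("nan")


def _gene_subset(dataset: CohortDataset, gene_variants: Sequence[str | int]):
    """Genotypes over the gene's variants with listwise exclusion of samples
    missing any call in the gene."""
    if len(gene_variants) == 0:
        raise ValueError("gene variant list is empty")
    idx = [dataset.variant_index(v) for v in gene_variants]
    geno = dataset.genotypes[:, idx]
    complete = (geno != MISSING).all(axis=1)
    return geno[complete], dataset.case_mask[complete], complete


def collapse_patterns(
    dataset: CohortDataset, gene_variants: Sequence[str | int]
) -> list[GenotypePattern]:
    """Enumerate distinct non-reference genotype patterns with phenotype
    counts.  Pattern order is lexicographic for determinism."""
    geno, case, _ = _gene_subset(dataset, gene_variants)
    patterns: dict[tuple[int, ...], list[int]] = {}
    for row, is_case in zip(geno, case):
        key = tuple(int(g) for g in row)
        if all(g == 0 for g in key):
            continue
        counts = patterns.setdefault(key, [0, 0])
        counts[0 if is_case else 1] += 1
    return [
        GenotypePattern(
            pattern_key=key,
            n_total=nc + nu,
            n_case=nc,
            n_control=nu,
        )
        for key, (nc, nu) in sorted(patterns.items())
    ]


def kbac_statistic(
    case_counts: np.ndarray,
    totals: np.ndarray,
    n_case: int,
    n_control: int,
) -> float:
    """KBAC statistic for given per-pattern case counts (weights computed
    from the same counts)."""
    N = n_case + n_control
    w = np.array(
        [stats.hypergeom.cdf(x, N, n_case, n) for x, n in zip(case_counts, totals)]
    )
    return float((w * (case_counts / n_case - (totals - case_counts) / n_control)).sum())


def kbac_test(
    patterns: Sequence[GenotypePattern],
    n_case: int,
    n_control: int,
    n_perm: int = 10000,
    seed: int = 0,
    early_stop_p: float | None = 0.1,
    batch_size: int = 1000,
) -> tuple[float, float]:
    """One-sided (risk) KBAC permutation test.

    Returns ``(statistic, p)`` with ``p = (1 + hits) / (1 + n_done)`` where
    hits counts permuted statistics >= the observed one.  Permutation stops
    early once the accumulated hit count already guarantees that the full-run
    p-value would exceed ``early_stop_p`` (the reported p is then computed on
    the permutations actually run, and is itself >= that threshold).
    Weights are recomputed for every permuted labeling.  With no patterns
    the test is defined as (0, 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not patterns:
        return 0.0, 1.0
    N = n_case + n_control
    totals = np.array([p.n_total for p in patterns], dtype=np.int64)
    obs_cases = np.array([p.n_case for p in patterns], dtype=np.int64)
    if totals.sum() > N:
        raise ValueError("pattern carriers exceed the sample size")

    observed = kbac_statistic(obs_cases, totals, n_case, n_control)

    # per-pattern weight lookup tables over all possible case counts
    cdf_tables = [
        stats.hypergeom.cdf(np.arange(n + 1), N, n_case, n) for n in totals
    ]
    colors = np.append(totals, N - totals.sum())
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    tol = 1e-12
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        draws = rng.multivariate_hypergeometric(colors, n_case, size=b)[:, : len(totals)]
        stat = np.zeros(b)
        for i, cdf in enumerate(cdf_tables):
            x = draws[:, i]
            stat += cdf[x] * (x / n_case - (totals[i] - x) / n_control)
        hits += int((stat >= observed - tol).sum())
        done += b
        if early_stop_p is not None and (1 + hits) > early_stop_p * (1 + n_perm):
            break
    return observed, (1 + hits) / (1 + done)


def cmc_test(
    dataset: CohortDataset,
    gene_variants: Sequence[str | int],
    adjust: Sequence[str] = (),
) -> dict:
    """CMC collapsing test: exact test + Haldane-corrected crude OR on the
    carries-any-qualifying-variant indicator; a covariate-adjusted logistic
    OR is reported alongside when ``adjust`` is non-empty (both retained,
    labeled -- neither replaces the other)."""
    geno, case, complete = _gene_subset(dataset, gene_variants)
    carrier = (geno >= 1).any(axis=1)
    table = CarrierTable(
        int((carrier & case).sum()),
        int((~carrier & case).sum()),
        int((carrier & ~case).sum()),
        int((~carrier & ~case).sum()),
    )
    out = {
        "table": table,
        "carriers_case": table.a,
        "carriers_control": table.c,
        "degenerate": False,
        "cmc_or_adjusted": None,
    }
    if carrier.all() or not carrier.any():
        out.update(
            degenerate=True,
            cmc_or=float("nan"),
            cmc_ci=(float("nan"), float("nan")),
            cmc_p=float("nan"),
        )
        return out
    res = fisher_assoc(table)
    out.update(cmc_or=res.or_point, cmc_ci=(res.ci_low, res.ci_high), cmc_p=res.p)

    if adjust:
        samples = dataset.samples.loc[complete]
        cols = {"carrier": carrier.astype(float)}
        for name in adjust:
            cols[name] = exposure_values(samples, name)
        X = pd.DataFrame(cols, index=samples.index)
        keep = np.isfinite(X.to_numpy(float)).all(axis=1)
        X = sm.add_constant(X.loc[keep], has_constant="add")
        y = case.astype(float)[keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if bool(fit.mle_retvals.get("converged", False)):
                    out["cmc_or_adjusted"] = float(np.exp(fit.params["carrier"]))
            except Exception:
                pass
    return out


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def exome_scan(
    dataset: CohortDataset,
    gene_map: Mapping[str, Sequence[str | int]],
    n_perm: int = 10000,
    seed: int = 0,
    adjust: Sequence[str] = (),
) -> pd.DataFrame:
    """Run KBAC and CMC per gene with BH-FDR across genes per test;
    returns a table ranked by CMC p-value."""
    if not gene_map:
        raise ValueError("gene_map is empty")
    rows = []
    for i, (gene, variants) in enumerate(sorted(gene_map.items())):
        patterns = collapse_patterns(dataset, variants)
        geno, case, _ = _gene_subset(dataset, variants)
        stat, p_kbac = kbac_test(
            patterns,
            int(case.sum()),
            int((~case).sum()),
            n_perm=n_perm,
            seed=_child_seed(seed, i),
        )
        cmc = cmc_test(dataset, variants, adjust=adjust)
        rows.append(
            {
                "gene": gene,
                "n_variants": len(variants),
                "n_patterns": len(patterns),
                "carriers_case": cmc["carriers_case"],
                "carriers_control": cmc["carriers_control"],
                "kbac_stat": stat,
                "kbac_p": p_kbac,
                "cmc_or": cmc.get("cmc_or", float("nan")),
                "cmc_ci_low": cmc.get("cmc_ci", (np.nan, np.nan))[0],
                "cmc_ci_high": cmc.get("cmc_ci", (np.nan, np.nan))[1],
                "cmc_p": cmc.get("cmc_p", float("nan")),
                "cmc_or_adjusted": cmc.get("cmc_or_adjusted"),
                "degenerate": cmc["degenerate"],
            }
        )
    df = pd.DataFrame(rows)
    ok = ~df["cmc_p"].isna()
    df["kbac_q"] = bh_fdr(df["kbac_p"].tolist())
    df.loc[ok, "cmc_q"] = bh_fdr(df.loc[ok, "cmc_p"].tolist())
    return df.sort_values("cmc_p", ignore_index=True)
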