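"""Candidate-gene prioritization from constraint, phenotype relevance and
association evidence."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: upper CI bound below which a gene's LoF observed/expected ratio indicates
#: strong selective intolerance
CONSTRAINT_UPPER_BOUND = 0.35

EVIDENCE_FLAGS = ("known_lc_locus", "clinvar_pathogenic", "constraint_intolerant")


@dataclass(frozen=True)
class ConstraintRecord:
    """Per-gene constraint (LoF o/e with 90% CI) and phenotype-relevance
    score, plus any externally supplied evidence flags."""

    gene: str
    oe: float | None = None
    oe_ci_low: float | None = None
    oe_ci_high: float | None = None
    phenotype_score: float = 0.0
    phenotype: str = ""
    evidence_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.oe is not None and self.oe < 0:
            raise ValueError("o/e must be non-negative")
        if not self.evidence_flags <= set(EVIDENCE_FLAGS):
            raise ValueError(f"unknown evidence flags: {set(self.evidence_flags) - set(EVIDENCE_FLAGS)}")
        if not 0.0 <= self.phenotype_score <= 1.0:
            raise ValueError("phenotype_score must lie in [0, 1]")


def constraint_flag(record: ConstraintRecord) -> bool:
    """True iff the upper bound of the LoF o/e 90% CI is strictly below
    0.35 (strong intolerance to loss of function).  A missing CI yields
    False (missing data, not evidence of tolerance)."""
    if record.oe_ci_high is None:
        return False
    return record.oe_ci_high < CONSTRAINT_UPPER_BOUND


def rank_candidates(
    records: Sequence[ConstraintRecord],
    burden_q: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Deterministic candidate ranking.

    Order: number of evidence flags (constraint intolerance added
    automatically from :func:`constraint_flag`) descending, burden FDR q
    ascending, phenotype score descending, gene symbol ascending.
    """
    genes = [r.gene for r in records]
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate gene rows")
    burden_q = burden_q or {}
    rows = []
    for r in records:
        flags = set(r.evidence_flags)
        if constraint_flag(r):
            flags.add("constraint_intolerant")
        rows.append(
            {
                "gene": r.gene,
                "n_evidence_flags": len(flags),
                "evidence_flags": ",".join(sorted(flags)),
                "constraint_intolerant": constraint_flag(r),
                "oe": r.oe,
                "oe_ci_high": r.oe_ci_high,
                "phenotype_score": r.phenotype_score,
                "burden_q": burden_q.get(r.gene, float("inf")),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["n_evidence_flags", "burden_q", "phenotype_score", "gene"],
        ascending=[False, True, False, True],
        ignore_index=True,
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def load_discovery_gene_table() -> pd.DataFrame:
    """Packaged per-gene discovery summary (burden results, constraint o/e
    with 90% CI, phenotype-relevance score) for the candidate genes."""
    with resources.files("carrierscan.data").joinpath("discovery_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def constraint_records_from_table(df: pd.DataFrame) -> list[ConstraintRecord]:
    return [
        ConstraintRecord(
            gene=str(r.gene),
            oe=float(r.oe),
            oe_ci_low=float(r.oe_ci_low),
            oe_ci_high=float(r.oe_ci_high),
            phenotype_score=float(r.phenotype_score),
            phenotype=str(r.phenotype),
        )
        for r in df.itertuples()
    ]
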