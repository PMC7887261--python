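"""Call/sample QC and the three-step rare-deleterious filtering cascade.

The cascade retains variants that are (1) rare in the reference panel
(MAF < 1% by default), (2) of a consequence class with plausible functional
impact -- missense, protein-truncating, or regulatory (UTR / essential
splice) -- with indels capped at 21 bp, and (3) supported by a consensus of
deleteriousness predictors (>= 4 of 6 tools), with protein-truncating
variants passing step 3 unconditionally.  Rare variants with a ClinVar
classification of pathogenic / likely pathogenic / VUS are rescued into the
candidate set regardless of steps 2-3.  Every step reports survivor counts
for an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .types import (
    CLINVAR_RESCUE,
    MISSING,
    REGULATORY,
    TRUNCATING,
    CohortDataset,
    VariantRecord,
)


class QcError(ValueError):
    """Invalid input to a QC operation (e.g. absent call metadata)."""


@dataclass(frozen=True)
class QcThresholds:
    """QC and filtering thresholds; all boundaries are inclusive exactly as
    stated (quality >= 20, depth >= 10, AB >= 0.2, call rate >= 0.85,
    completion >= 0.95) except the rarity cut which is strict (MAF < 1%)."""

    min_quality: float = 20.0
    min_depth: int = 10
    min_allele_balance: float = 0.2
    min_call_rate: float = 0.85
    min_completion: float = 0.95
    max_ibs: float = 0.10
    min_ibs_sites: int = 20
    het_rate_sd: float = 3.0
    min_het_sites: int = 50
    max_ref_maf: float = 0.01
    min_deleterious_votes: int = 4
    max_indel_len: int = 21

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("min_allele_balance", 0, 1),
            ("min_call_rate", 0, 1),
            ("min_completion", 0, 1),
            ("max_ibs", 0, 1),
            ("max_ref_maf", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not 0 <= self.min_deleterious_votes <= 6:
            raise ValueError("min_deleterious_votes must lie in 0..6")
        if self.min_quality < 0 or self.min_depth < 0 or self.max_indel_len < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class CallQcReport:
    calls_failed_quality: int = 0
    calls_failed_depth: int = 0
    calls_failed_allele_balance: int = 0
    variants_failed_call_rate: int = 0
    variants_in_mask: int = 0
    variants_region_flagged: int = 0
    n_variants_in: int = 0
    n_variants_out: int = 0


def _build_mask_trees(masks: Iterable[tuple[str, int, int]] | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if masks is None:
        return trees
    for chrom, start, end in masks:
        trees.setdefault(str(chrom), IntervalTree()).addi(int(start), int(end))
    return trees


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file (0-based half-open intervals)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def call_qc(
    dataset: CohortDataset,
    thresholds: QcThresholds = QcThresholds(),
    masks: Iterable[tuple[str, int, int]] | None = None,
) -> tuple[CohortDataset, CallQcReport]:
    """Call-level and variant-level QC.

    Calls failing quality/depth (or allele balance, for heterozygous calls)
    are set to missing; variants with post-QC call rate below the threshold,
    overlapping a mask interval (BED convention: 0-based half-open), or
    carrying a low-complexity/segmental-duplication flag are removed.
    """
    for name in ("quality", "depth", "allele_balance"):
        if getattr(dataset, name) is None:
            raise QcError(f"call-level metadata {name!r} is absent")

    report = CallQcReport(n_variants_in=dataset.n_variants)
    genos = dataset.genotypes.copy()
    called = genos != MISSING

    fail_q = called & ~(dataset.quality >= thresholds.min_quality)
    fail_d = called & ~(dataset.depth >= thresholds.min_depth)
    het = genos == 1
    ab = dataset.allele_balance
    fail_ab = het & called & ~(ab >= thresholds.min_allele_balance)
    report.calls_failed_quality = int(fail_q.sum())
    report.calls_failed_depth = int(fail_d.sum())
    report.calls_failed_allele_balance = int(fail_ab.sum())
    genos[fail_q | fail_d | fail_ab] = MISSING

    call_rate = (genos != MISSING).mean(axis=0)
    pass_rate = call_rate >= thresholds.min_call_rate
    report.variants_failed_call_rate = int((~pass_rate).sum())

    trees = _build_mask_trees(masks)
    in_mask = np.zeros(dataset.n_variants, dtype=bool)
    for j, v in enumerate(dataset.variants):
        tree = trees.get(v.chrom)
        if tree is not None and tree.overlaps_point(v.pos - 1):  # VCF pos is 1-based
            in_mask[j] = True
    report.variants_in_mask = int(in_mask.sum())

    flagged = np.array([bool(v.region_flags) for v in dataset.variants])
    report.variants_region_flagged = int(flagged.sum())

    keep = pass_rate & ~in_mask & ~flagged
    report.n_variants_out = int(keep.sum())
    out = dataset.with_genotypes(genos).subset(variant_mask=keep)
    return out, report


@dataclass(frozen=True)
class SampleExclusion:
    sample_id: str
    reason: str


def _infer_sex(genos_x: np.ndarray) -> np.ndarray:
    """X-heterozygosity sex inference: het rate < 0.2 => male."""
    called = genos_x != MISSING
    n_called = called.sum(axis=1)
    het_rate = np.divide(
        (genos_x == 1).sum(axis=1),
        n_called,
        out=np.zeros(genos_x.shape[0]),
        where=n_called > 0,
    )
    return np.where(het_rate < 0.2, "male", "female")


def _ibs_sharing(genos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise rare-allele sharing fraction.

    For each sample pair: among sites where both calls are present and at
    least one carries an alternate allele, the fraction with identical
    genotypes.  Duplicates score 1; unrelated samples score near 0 on rare
    variants.  Returns (sharing fraction, informative-site count); pairs
    with no informative site score 0.
    """
    called = (genos != MISSING).astype(np.float32)
    g1 = (genos == 1).astype(np.float32)
    g2 = (genos == 2).astype(np.float32)
    alt = ((genos >= 1)).astype(np.float32)
    # identical non-reference genotypes at sites where both are called
    same = g1 @ g1.T + g2 @ g2.T
    # sites with both called and >=1 alternate allele in the pair
    t1 = alt @ called.T
    t3 = alt @ alt.T
    informative = t1 + t1.T - t3
    share = np.divide(
        same, informative, out=np.zeros_like(same), where=informative > 0
    )
    return share, informative


def sample_qc(
    dataset: CohortDataset,
    thresholds: QcThresholds = QcThresholds(),
    reported_sex: Mapping[str, str] | None = None,
) -> tuple[CohortDataset, list[SampleExclusion]]:
    """Exclude samples with low completion, outlying heterozygosity,
    sex discordance (X-heterozygosity inference, skipped when no X variants
    are present), or unexpected relatedness (rare-allele IBS sharing above
    the threshold; of each related pair, the member with the lower
    completion rate is dropped)."""
    ids = dataset.samples["sample_id"].tolist()
    if len(ids) != len(set(ids)):
        raise QcError("duplicate sample IDs")
    if dataset.n_samples < 2:
        raise QcError("sample QC requires at least two samples")

    genos = dataset.genotypes
    called = genos != MISSING
    completion = called.mean(axis=1)
    exclusions: list[SampleExclusion] = []
    excluded = np.zeros(dataset.n_samples, dtype=bool)

    for i in np.flatnonzero(completion < thresholds.min_completion):
        exclusions.append(SampleExclusion(ids[i], "completion"))
        excluded[i] = True

    n_called = called.sum(axis=1)
    het_rate = np.divide(
        (genos == 1).sum(axis=1), n_called, out=np.zeros(dataset.n_samples), where=n_called > 0
    )
    sd = het_rate.std(ddof=0)
    # heterozygosity is only a meaningful per-sample statistic over many
    # sites; a small rare-variant panel would flag every multi-carrier
    if sd > 0 and dataset.n_variants >= thresholds.min_het_sites:
        mean = het_rate.mean()
        outlier = np.abs(het_rate - mean) > thresholds.het_rate_sd * sd
        for i in np.flatnonzero(outlier & ~excluded):
            exclusions.append(SampleExclusion(ids[i], "heterozygosity"))
            excluded[i] = True

    x_cols = np.array([v.chrom in ("X", "chrX") for v in dataset.variants])
    if reported_sex is not None and x_cols.any():
        inferred = _infer_sex(genos[:, x_cols])
        for i, sid in enumerate(ids):
            rep = reported_sex.get(sid)
            if rep is not None and not excluded[i] and inferred[i] != rep:
                exclusions.append(SampleExclusion(sid, "sex_discordance"))
                excluded[i] = True

    share, informative = _ibs_sharing(genos)
    # a sharing fraction over a handful of rare sites is meaningless: only
    # pairs with enough informative comparisons are evaluated
    flagged_pairs = np.argwhere(
        np.triu(
            (share > thresholds.max_ibs) & (informative >= thresholds.min_ibs_sites), k=1
        )
    )
    for i, j in flagged_pairs:
        if excluded[i] or excluded[j]:
            continue
        drop = i if completion[i] < completion[j] else j
        exclusions.append(SampleExclusion(ids[drop], "relatedness"))
        excluded[drop] = True

    return dataset.subset(sample_mask=~excluded), exclusions


def consensus_deleterious(
    variant: VariantRecord, thresholds: QcThresholds = QcThresholds()
) -> bool:
    """Deleteriousness consensus: >= 4 of 6 tool votes, with missing verdicts
    counted as non-deleterious; protein-truncating consequences pass
    unconditionally."""
    if variant.is_truncating:
        return True
    votes = sum(v == "deleterious" for v in variant.verdicts)
    return votes >= thresholds.min_deleterious_votes


_STEP2_CLASSES = frozenset({"missense"}) | TRUNCATING | frozenset({"utr3", "utr5"})


@dataclass
class CascadeReport:
    n_input: int = 0
    pass_step1_maf: int = 0
    pass_step2_class: int = 0
    pass_step3_deleterious: int = 0
    clinvar_rescued: int = 0
    n_final: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_cascade(
    variants: Sequence[VariantRecord],
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[list[VariantRecord], CascadeReport]:
    """Three-step rare-deleterious cascade with ClinVar rescue.

    Step 1 (rarity) applies to everything; the ClinVar rescue unions any
    step-1-passing variant classified pathogenic / likely pathogenic / VUS
    back into the candidate set even if it fails steps 2-3.  A variant with
    no reference MAF annotation raises ``QcError`` rather than being treated
    as rare.
    """
    report = CascadeReport(n_input=len(variants))
    for v in variants:
        if v.ref_maf is None:
            raise QcError(f"variant {v.key} has no reference MAF annotation")

    step1 = [v for v in variants if v.ref_maf < thresholds.max_ref_maf]
    report.pass_step1_maf = len(step1)
    step2 = [
        v
        for v in step1
        if v.consequence in _STEP2_CLASSES and v.indel_length <= thresholds.max_indel_len
    ]
    report.pass_step2_class = len(step2)
    step3 = [v for v in step2 if consensus_deleterious(v, thresholds)]
    report.pass_step3_deleterious = len(step3)

    rescued = [v for v in step1 if v.clinvar in CLINVAR_RESCUE]
    kept_keys = {v.key for v in step3}
    report.clinvar_rescued = sum(v.key not in kept_keys for v in rescued)

    final_keys = kept_keys | {v.key for v in rescued}
    final = [v for v in variants if v.key in final_keys]
    report.n_final = len(final)
    return final, report
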