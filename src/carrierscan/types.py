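"""Core domain containers shared across the pipeline.

Genotypes are coded 0/1/2 alternate-allele counts with ``-1`` for missing
calls.  A *carrier* throughout the package means a sample with genotype >= 1
(dominant coding), which is the unit every association operation works on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: consequence classes understood by the filtering cascade
CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gain",
        "frameshift",
        "inframe_indel",
        "splice_acceptor",
        "splice_donor",
        "start_loss",
        "utr3",
        "utr5",
        "other",
    }
)

#: protein-truncating (loss-of-function) consequence classes
TRUNCATING = frozenset(
    {"stop_gain", "frameshift", "splice_acceptor", "splice_donor", "start_loss"}
)

#: the 3' / 5' UTR plus essential-splice classes counted as "regulatory"
REGULATORY = frozenset({"utr3", "utr5", "splice_acceptor", "splice_donor"})

VERDICTS = ("deleterious", "tolerated", "missing")
CLINVAR_CLASSES = (
    "pathogenic",
    "likely_pathogenic",
    "vus",
    "benign_or_likely_benign",
    "none",
)
REGION_FLAGS = frozenset({"low_complexity", "segdup"})

#: ClinVar classes that rescue a rare variant into the candidate set
CLINVAR_RESCUE = frozenset({"pathogenic", "likely_pathogenic", "vus"})


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant.

    ``verdicts`` holds the six deleteriousness predictions (e.g. SIFT,
    PolyPhen-2, MutationTaster, MutationAssessor, FATHMM, FATHMM-MKL) as
    ``deleterious`` / ``tolerated`` / ``missing`` labels; the package never
    recomputes them, it only counts votes.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str | None = None
    gene: str = ""
    consequence: str = "other"
    ref_maf: float | None = None
    verdicts: tuple[str, ...] = ("missing",) * 6
    clinvar: str = "none"
    region_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        if self.ref_maf is not None and not (0.0 <= self.ref_maf <= 1.0):
            raise ValueError(f"ref_maf must lie in [0, 1], got {self.ref_maf}")
        if self.clinvar not in CLINVAR_CLASSES:
            raise ValueError(f"unknown ClinVar class {self.clinvar!r}")
        for v in self.verdicts:
            if v not in VERDICTS:
                raise ValueError(f"unknown verdict {v!r}")
        if not self.region_flags <= REGION_FLAGS:
            raise ValueError(f"unknown region flags {set(self.region_flags) - REGION_FLAGS}")

    @property
    def indel_length(self) -> int:
        """Absolute length difference between ref and alt (0 for SNVs)."""
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_truncating(self) -> bool:
        return self.consequence in TRUNCATING

    @property
    def key(self) -> str:
        return self.variant_id or f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


SAMPLE_COLUMNS = [
    "sample_id",
    "phenotype",
    "age",
    "sex",
    "smoking",
    "pack_years",
    "fhlc",
    "cohort",
]


@dataclass
class CohortDataset:
    """Genotype matrix joined to sample phenotypes and per-call metadata.

    ``samples`` is a DataFrame with columns ``sample_id, phenotype (1=case,
    0=control), age, sex, smoking, pack_years, fhlc, cohort``.  ``genotypes``
    is an ``(n_samples, n_variants)`` int array in {0,1,2,-1}.  Call-level
    ``quality``/``depth``/``allele_balance`` share that shape; allele balance
    is NaN except for non-missing heterozygous calls.
    """

    samples: pd.DataFrame
    variants: list[VariantRecord]
    genotypes: np.ndarray
    quality: np.ndarray | None = None
    depth: np.ndarray | None = None
    allele_balance: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"samples table lacks columns: {missing_cols}")
        n_s, n_v = self.genotypes.shape
        if n_s != len(self.samples):
            raise ValueError(
                f"genotype rows ({n_s}) != number of samples ({len(self.samples)})"
            )
        if n_v != len(self.variants):
            raise ValueError(
                f"genotype columns ({n_v}) != number of variants ({len(self.variants)})"
            )
        for name in ("quality", "depth", "allele_balance"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.genotypes.shape:
                raise ValueError(f"{name} shape {arr.shape} != genotype shape")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes must be 0, 1, 2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def variant_index(self, variant: str | int) -> int:
        if isinstance(variant, (int, np.integer)):
            if not 0 <= variant < self.n_variants:
                raise KeyError(f"variant index {variant} out of range")
            return int(variant)
        try:
            return self.variant_keys.index(variant)
        except ValueError:
            raise KeyError(f"unknown variant {variant!r}") from None

    @property
    def case_mask(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy() == 1

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "CohortDataset":
        """Return a copy restricted to the selected samples/variants."""

        def take(arr, sm, vm):
            if arr is None:
                return None
            out = arr
            if sm is not None:
                out = out[sm]
            if vm is not None:
                out = out[:, vm]
            return out.copy()

        samples = self.samples if sample_mask is None else self.samples.loc[sample_mask]
        variants = (
            self.variants
            if variant_mask is None
            else [v for v, keep in zip(self.variants, variant_mask) if keep]
        )
        return CohortDataset(
            samples=samples.reset_index(drop=True),
            variants=list(variants),
            genotypes=take(self.genotypes, sample_mask, variant_mask),
            quality=take(self.quality, sample_mask, variant_mask),
            depth=take(self.depth, sample_mask, variant_mask),
            allele_balance=take(self.allele_balance, sample_mask, variant_mask),
        )

    def with_genotypes(self, genotypes: np.ndarray) -> "CohortDataset":
        return replace(self, genotypes=genotypes)


def exposure_values(samples: pd.DataFrame, name: str) -> np.ndarray:
    """Numeric coding of a covariate column for regression/interaction terms.

    Binary covariates are coded 1 = male / ever-smoker / positive family
    history; ``age`` and ``pack_years`` are passed through as-is.  ``fhlc``
    'unknown' codes to NaN so downstream fits can drop those samples.
    """
    if name in ("age", "pack_years"):
        return samples[name].to_numpy(dtype=float)
    if name == "sex":
        return (samples["sex"].to_numpy() == "male").astype(float)
    if name == "smoking":
        return (samples["smoking"].to_numpy() == "ever").astype(float)
    if name == "fhlc":
        vals = samples["fhlc"].to_numpy()
        out = np.where(vals == "yes", 1.0, np.where(vals == "no", 0.0, np.nan))
        return out
    raise KeyError(f"unknown exposure/covariate {name!r}")
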