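"""Case-control cohort simulator for rare-variant association analyses.

Real rare-variant studies of this design are controlled-access, so every
downstream stage of the package is exercised on cohorts generated here.  The
generator emulates the statistical structure the analyses assume:

* rare alleles (reference MAF well below 1%) drawn log-uniformly,
* Hardy-Weinberg genotype sampling per variant,
* a logistic disease model with planted per-variant log odds ratios acting
  on carrier status (dominant coding) plus optional gene-by-environment
  product terms,
* covariates patterned on a smoking-enriched lung-cancer case-control study
  (age, sex, smoking status, pack-years, first-degree family history),
* per-call quality / read depth / allele balance and completely-at-random
  missingness, so call-level QC has something to act on,
* multi-cohort validation designs in which some strata contribute only
  cases and others only controls, all drawn from one shared generative
  model so a single true odds ratio is common to every stratum.

Everything is deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .types import MISSING, TRUNCATING, CohortDataset, VariantRecord


class CalibrationError(RuntimeError):
    """Raised when the requested case fraction cannot be reached."""


@dataclass(frozen=True)
class CovariateModel:
    """Distributions for sample covariates.

    Defaults mirror a smoking-enriched case-control design: mean age in the
    early 60s, a modest male excess, three quarters ever-smokers, and
    gamma-distributed pack-years among smokers (never-smokers have zero
    pack-years by definition).
    """

    age_mean: float = 62.0
    age_sd: float = 11.0
    age_min: float = 20.0
    age_max: float = 95.0
    p_male: float = 0.58
    p_ever_smoker: float = 0.75
    pack_years_shape: float = 2.0
    pack_years_scale: float = 20.0
    p_fhlc_yes: float = 0.25
    p_fhlc_unknown: float = 0.10


@dataclass(frozen=True)
class CallQualityModel:
    """Per-call metadata distributions (Phred-like quality, depth, AB)."""

    quality_mean: float = 60.0
    quality_sd: float = 15.0
    depth_mean: float = 52.0
    ab_concentration: float = 20.0


@dataclass(frozen=True)
class StratumSpec:
    """One cohort in a multi-cohort validation design.

    ``contributes`` is ``cases``, ``controls`` or ``both``; ``n`` is the
    cohort size (for ``both`` it is split by the configured case fraction).
    """

    label: str
    contributes: str
    n: int

    def __post_init__(self) -> None:
        if self.contributes not in ("cases", "controls", "both"):
            raise ValueError(f"contributes must be cases/controls/both, got {self.contributes!r}")
        if self.n <= 0:
            raise ValueError("stratum size must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 1045
    n_controls: int = 885
    n_variants: int = 25
    maf_range: tuple[float, float] = (1e-4, 0.01)
    planted_effects: Mapping[int, float] = field(default_factory=dict)
    covariate_model: CovariateModel = CovariateModel()
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    gxe_effects: Mapping[tuple[int, str], float] = field(default_factory=dict)
    missing_rate: float = 0.02
    call_quality_model: CallQualityModel = CallQualityModel()
    seed: int = 0
    strata_design: tuple[StratumSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_variants <= 0:
            raise ValueError("n_cases, n_controls and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic substreams per purpose
    return np.random.default_rng([int(config.seed), stream])


def draw_mafs(config: SimulationConfig) -> np.ndarray:
    """Log-uniform MAFs in ``config.maf_range``; shared by genotype and
    annotation simulation so reference MAFs are consistent with sampling."""
    rng = _rng(config, 0)
    lo, hi = config.maf_range
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=config.n_variants))


def _draw_covariates(rng: np.random.Generator, model: CovariateModel, n: int) -> pd.DataFrame:
    age = np.clip(rng.normal(model.age_mean, model.age_sd, n), model.age_min, model.age_max)
    sex = np.where(rng.random(n) < model.p_male, "male", "female")
    smoking = np.where(rng.random(n) < model.p_ever_smoker, "ever", "never")
    pack_years = np.where(
        smoking == "ever",
        rng.gamma(model.pack_years_shape, model.pack_years_scale, n),
        0.0,
    )
    u = rng.random(n)
    fhlc = np.where(
        u < model.p_fhlc_yes,
        "yes",
        np.where(u < model.p_fhlc_yes + model.p_fhlc_unknown, "unknown", "no"),
    )
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "sex": sex,
            "smoking": smoking,
            "pack_years": np.round(pack_years, 1),
            "fhlc": fhlc,
        }
    )


def _exposure_column(cov: pd.DataFrame, name: str) -> np.ndarray:
    if name == "sex":
        return (cov["sex"].to_numpy() == "male").astype(float)
    if name == "smoking":
        return (cov["smoking"].to_numpy() == "ever").astype(float)
    if name == "fhlc":
        return (cov["fhlc"].to_numpy() == "yes").astype(float)
    if name in ("age", "pack_years"):
        return cov[name].to_numpy(dtype=float)
    raise KeyError(f"unknown covariate {name!r}")


def _linear_predictor(
    config: SimulationConfig,
    genotypes: np.ndarray,
    cov: pd.DataFrame,
) -> np.ndarray:
    """Risk score without intercept: planted carrier effects + covariate
    main effects + carrier-by-exposure interactions (dominant coding)."""
    eta = np.zeros(len(cov))
    carrier = genotypes >= 1
    for idx, beta in config.planted_effects.items():
        eta += beta * carrier[:, idx]
    for name, beta in config.covariate_effects.items():
        eta += beta * _exposure_column(cov, name)
    for (idx, name), beta in config.gxe_effects.items():
        eta += beta * carrier[:, idx] * _exposure_column(cov, name)
    return eta


def _calibrate_intercept(config: SimulationConfig, mafs: np.ndarray) -> float:
    """Choose the logistic intercept so the population case fraction matches
    the requested one, by Monte-Carlo averaging over the generative model."""
    target = config.case_fraction
    if not config.planted_effects and not config.covariate_effects and not config.gxe_effects:
        return float(logit(target))
    rng = _rng(config, 1)
    n_calib = 20000
    genotypes = rng.binomial(2, mafs, size=(n_calib, config.n_variants)).astype(np.int8)
    cov = _draw_covariates(rng, config.covariate_model, n_calib)
    eta = _linear_predictor(config, genotypes, cov)

    def mean_risk(b0: float) -> float:
        return float(expit(b0 + eta).mean()) - target

    try:
        return float(brentq(mean_risk, -40.0, 40.0, xtol=1e-10))
    except ValueError as err:  # pragma: no cover - requires pathological config
        raise CalibrationError(
            f"cannot calibrate intercept for case fraction {target:.3f}: {err}"
        ) from err


def _draw_pool(
    config: SimulationConfig,
    mafs: np.ndarray,
    beta0: float,
    rng: np.random.Generator,
    n_cases: int,
    n_controls: int,
    max_batches: int = 60,
):
    """Draw individuals from the generative model until the requested case
    and control counts are available; returns (genotypes, covariates)."""
    need = n_cases + n_controls
    batch = max(2000, int(1.5 * need))
    g_cases, g_controls, c_cases, c_controls = [], [], [], []
    have_cases = have_controls = 0
    for _ in range(max_batches):
        genotypes = rng.binomial(2, mafs, size=(batch, config.n_variants)).astype(np.int8)
        cov = _draw_covariates(rng, config.covariate_model, batch)
        p = expit(beta0 + _linear_predictor(config, genotypes, cov))
        is_case = rng.random(batch) < p
        if have_cases < n_cases:
            g_cases.append(genotypes[is_case])
            c_cases.append(cov.loc[is_case])
            have_cases += int(is_case.sum())
        if have_controls < n_controls:
            g_controls.append(genotypes[~is_case])
            c_controls.append(cov.loc[~is_case])
            have_controls += int((~is_case).sum())
        if have_cases >= n_cases and have_controls >= n_controls:
            g = np.vstack([np.vstack(g_cases)[:n_cases], np.vstack(g_controls)[:n_controls]])
            c = pd.concat(
                [pd.concat(c_cases).iloc[:n_cases], pd.concat(c_controls).iloc[:n_controls]],
                ignore_index=True,
            )
            phen = np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
            return g, c, phen
    raise CalibrationError(
        "could not accumulate the requested case/control counts; the planted "
        "effects make the configured case fraction unreachable"
    )


def _inject_call_metadata(
    config: SimulationConfig, genotypes: np.ndarray, rng: np.random.Generator
):
    qm = config.call_quality_model
    shape = genotypes.shape
    quality = np.clip(rng.normal(qm.quality_mean, qm.quality_sd, shape), 0.0, None)
    depth = rng.poisson(qm.depth_mean, shape).astype(np.int32)
    ab = np.full(shape, np.nan)
    het = genotypes == 1
    ab[het] = rng.beta(qm.ab_concentration, qm.ab_concentration, int(het.sum()))
    if config.missing_rate > 0:
        miss = rng.random(shape) < config.missing_rate
        genotypes = genotypes.copy()
        genotypes[miss] = MISSING
        quality[miss] = np.nan
        depth[miss] = 0
        ab[miss] = np.nan
    return genotypes, quality, depth, ab


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Simulate a case-control cohort under the configured disease model.

    Phenotypes follow a logistic model whose intercept is calibrated so the
    population case fraction equals ``n_cases / (n_cases + n_controls)``;
    sampling then retains exactly the requested numbers of cases and
    controls (cases first).  Because the planted effects act on carrier
    status, the carrier odds ratio recovered downstream is the exponential
    of the planted log-OR, invariant under this retrospective sampling.
    """
    mafs = draw_mafs(config)
    beta0 = _calibrate_intercept(config, mafs)
    rng = _rng(config, 2)
    genotypes, cov, phen = _draw_pool(
        config, mafs, beta0, rng, config.n_cases, config.n_controls
    )
    genotypes, quality, depth, ab = _inject_call_metadata(config, genotypes, rng)
    n = len(phen)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "phenotype": phen,
            "cohort": "SIM",
        }
    ).join(cov.reset_index(drop=True))
    samples = samples[
        ["sample_id", "phenotype", "age", "sex", "smoking", "pack_years", "fhlc", "cohort"]
    ]
    variants = default_variants(config, mafs)
    return CohortDataset(
        samples=samples,
        variants=variants,
        genotypes=genotypes,
        quality=quality,
        depth=depth,
        allele_balance=ab,
    )


def default_variants(config: SimulationConfig, mafs: np.ndarray | None = None) -> list[VariantRecord]:
    """Placeholder variant records (SNVs 1 kb apart on chr1) carrying the
    simulated MAF as the reference-panel MAF; richer annotations come from
    :func:`simulate_annotations`."""
    if mafs is None:
        mafs = draw_mafs(config)
    return [
        VariantRecord(
            chrom="1",
            pos=1000 * (i + 1),
            ref="A",
            alt="C",
            variant_id=f"var{i:04d}",
            gene=f"GENE{i + 1}",
            consequence="missense",
            ref_maf=float(mafs[i]),
        )
        for i in range(config.n_variants)
    ]


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationProfile:
    """How a variant class looks to the annotation tools.

    ``p_deleterious`` is the per-tool probability of a 'deleterious' verdict
    (tools vote independently); ``p_verdict_missing`` the chance a tool has
    no prediction; ``clinvar_probs`` the distribution over ClinVar classes.
    """

    consequences: tuple[str, ...]
    p_deleterious: float
    p_verdict_missing: float = 0.05
    clinvar_probs: Mapping[str, float] = field(
        default_factory=lambda: {"none": 1.0}
    )
    region_flag_prob: float = 0.0


PROFILES: dict[str, AnnotationProfile] = {
    "deleterious_missense": AnnotationProfile(
        ("missense",),
        p_deleterious=0.9,
        clinvar_probs={"none": 0.6, "vus": 0.3, "likely_pathogenic": 0.05, "pathogenic": 0.05},
    ),
    "benign_missense": AnnotationProfile(
        ("missense",),
        p_deleterious=0.1,
        clinvar_probs={"none": 0.8, "benign_or_likely_benign": 0.2},
    ),
    "truncating": AnnotationProfile(
        tuple(sorted(TRUNCATING)),
        p_deleterious=0.9,
        clinvar_probs={"none": 0.4, "vus": 0.3, "likely_pathogenic": 0.1, "pathogenic": 0.2},
    ),
    "regulatory": AnnotationProfile(
        ("utr3", "utr5"),
        p_deleterious=0.3,
        clinvar_probs={"none": 0.8, "vus": 0.2},
    ),
    "neutral": AnnotationProfile(
        ("other",),
        p_deleterious=0.05,
        clinvar_probs={"none": 1.0},
    ),
}


def _alleles_for(consequence: str, rng: np.random.Generator) -> tuple[str, str]:
    if consequence == "frameshift":
        length = int(rng.choice([1, 2, 4, 5, 7, 8, 10, 11, 13, 16, 19]))  # not /3, <=21
        return "A" * (length + 1), "A"
    if consequence == "inframe_indel":
        length = int(rng.choice([3, 6, 9, 12, 15, 18, 21]))
        return "A" * (length + 1), "A"
    return "A", "C"


def simulate_annotations(
    config: SimulationConfig,
    causal_profile: Mapping[int, str | AnnotationProfile] | str | AnnotationProfile = "benign_missense",
    genes: Sequence[str] | None = None,
) -> list[VariantRecord]:
    """Generate annotated variant records matching the simulated MAFs.

    ``causal_profile`` maps variant index to a profile name (or profile
    object); a bare name/profile applies to every variant.  Reference MAFs
    equal the simulated sampling MAFs, so the rarity filter sees frequencies
    consistent with the genotype data.
    """
    mafs = draw_mafs(config)
    rng = _rng(config, 3)
    if isinstance(causal_profile, (str, AnnotationProfile)):
        causal_profile = {i: causal_profile for i in range(config.n_variants)}

    records: list[VariantRecord] = []
    for i in range(config.n_variants):
        prof = causal_profile.get(i, "benign_missense")
        if isinstance(prof, str):
            try:
                prof = PROFILES[prof]
            except KeyError:
                raise ValueError(f"unknown annotation profile {prof!r}") from None
        consequence = str(rng.choice(prof.consequences))
        ref, alt = _alleles_for(consequence, rng)
        u = rng.random(6)
        verdicts = tuple(
            "missing"
            if rng.random() < prof.p_verdict_missing
            else ("deleterious" if ui < prof.p_deleterious else "tolerated")
            for ui in u
        )
        classes = list(prof.clinvar_probs)
        probs = np.array([prof.clinvar_probs[c] for c in classes], dtype=float)
        clinvar = str(rng.choice(classes, p=probs / probs.sum()))
        flags = frozenset(
            f for f in ("low_complexity", "segdup") if rng.random() < prof.region_flag_prob
        )
        records.append(
            VariantRecord(
                chrom="1",
                pos=1000 * (i + 1),
                ref=ref,
                alt=alt,
                variant_id=f"var{i:04d}",
                gene=genes[i] if genes is not None else f"GENE{i + 1}",
                consequence=consequence,
                ref_maf=float(mafs[i]),
                verdicts=verdicts,
                clinvar=clinvar,
                region_flags=flags,
            )
        )
    return records


# ---------------------------------------------------------------------------
# multi-cohort validation strata
# ---------------------------------------------------------------------------

def make_validation_strata(
    config: SimulationConfig, variant: int = 0
) -> list[tuple[str, "CarrierTable"]]:
    """Carrier 2x2 tables for a multi-cohort validation design.

    All strata are drawn from the single generative model fixed by
    ``config`` (same MAFs and planted effects), so one true odds ratio is
    common to every stratum -- the assumption of a fixed-effects
    meta-analysis.  Case-only cohorts are paired with the next control-only
    cohort in the design order; ``both`` cohorts form a stratum on their
    own.  Raises ``ValueError`` for a case-only cohort with no control
    source to pair with.
    """
    from .assoc import CarrierTable  # local import to avoid a cycle

    if not config.strata_design:
        raise ValueError("strata_design is empty")
    mafs = draw_mafs(config)
    beta0 = _calibrate_intercept(config, mafs)

    def carriers(rng, n_cases, n_controls):
        genotypes, _, phen = _draw_pool(config, mafs, beta0, rng, max(n_cases, 1), max(n_controls, 1))
        carrier = genotypes[:, variant] >= 1
        case = phen == 1
        a = int(carrier[case][:n_cases].sum())
        c = int(carrier[~case][:n_controls].sum())
        return a, c

    out: list[tuple[str, CarrierTable]] = []
    pending_cases: tuple[str, int, int] | None = None  # label, n, a
    for k, spec in enumerate(config.strata_design):
        rng = _rng(config, 100 + k)
        if spec.contributes == "both":
            n_cases = max(1, round(spec.n * config.case_fraction))
            n_controls = max(1, spec.n - n_cases)
            a, c = carriers(rng, n_cases, n_controls)
            out.append(
                (spec.label, CarrierTable(a, n_cases - a, c, n_controls - c))
            )
        elif spec.contributes == "cases":
            if pending_cases is not None:
                raise ValueError(
                    f"case-only cohort {pending_cases[0]!r} has no paired control source"
                )
            a, _ = carriers(rng, spec.n, 0)
            pending_cases = (spec.label, spec.n, a)
        else:  # controls
            _, c = carriers(rng, 0, spec.n)
            if pending_cases is None:
                raise ValueError(
                    f"control-only cohort {spec.label!r} has no paired case source"
                )
            label, n_case, a = pending_cases
            out.append(
                (f"{label}/{spec.label}", CarrierTable(a, n_case - a, c, spec.n - c))
            )
            pending_cases = None
    if pending_cases is not None:
        raise ValueError(
            f"case-only cohort {pending_cases[0]!r} has no paired control source"
        )
    return out
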