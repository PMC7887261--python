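"""Flat-file interchange: VCF, annotation/phenotype/strata TSV, YAML config."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .assoc import CarrierTable
from .simulate import (
    CallQualityModel,
    CovariateModel,
    SimulationConfig,
    StratumSpec,
)
from .types import MISSING, CohortDataset, VariantRecord

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=carrierscan
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AB,Number=1,Type=Float,Description="Allele balance (het calls)">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(dataset: CohortDataset, path: str | Path) -> None:
    """Write genotypes as an uncompressed VCF with GT:GQ:DP:AB per call
    (1-based positions)."""
    path = Path(path)
    ids = dataset.samples["sample_id"].tolist()
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for j, v in enumerate(dataset.variants):
            calls = []
            for i in range(dataset.n_samples):
                g = int(dataset.genotypes[i, j])
                gq = dataset.quality[i, j] if dataset.quality is not None else np.nan
                dp = dataset.depth[i, j] if dataset.depth is not None else 0
                ab = (
                    dataset.allele_balance[i, j]
                    if dataset.allele_balance is not None
                    else np.nan
                )
                gq_s = "." if not math.isfinite(float(gq)) else str(int(round(float(gq))))
                ab_s = "." if not math.isfinite(float(ab)) else f"{float(ab):.3f}"
                calls.append(f"{_GT_CODE[g]}:{gq_s}:{int(dp)}:{ab_s}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.key}\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                f"GT:GQ:DP:AB\t" + "\t".join(calls) + "\n"
            )


def write_phenotypes(dataset: CohortDataset, path: str | Path) -> None:
    dataset.samples.to_csv(path, sep="\t", index=False)


def annotations_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {
            "variant_id": v.key,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "ref_maf": v.ref_maf,
            "clinvar": v.clinvar,
            "region_flags": ",".join(sorted(v.region_flags)),
        }
        for k, verdict in enumerate(v.verdicts):
            row[f"tool{k + 1}"] = verdict
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotations(variants: Sequence[VariantRecord], path: str | Path) -> None:
    annotations_frame(variants).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    out = []
    for r in df.itertuples():
        flags = frozenset(str(r.region_flags).split(",")) - {"", "nan"}
        out.append(
            VariantRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                variant_id=str(r.variant_id),
                gene=str(r.gene),
                consequence=str(r.consequence),
                ref_maf=None if pd.isna(r.ref_maf) else float(r.ref_maf),
                verdicts=tuple(str(getattr(r, f"tool{k + 1}")) for k in range(6)),
                clinvar=str(r.clinvar),
                region_flags=flags,
            )
        )
    return out


def read_strata(path: str | Path) -> list[tuple[str, CarrierTable]]:
    """Read a strata TSV (label, a, b, c, d)."""
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.label), CarrierTable(int(r.a), int(r.b), int(r.c), int(r.d)))
        for r in df.itertuples()
    ]


def write_strata(strata: Sequence[tuple[str, CarrierTable]], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"label": label, "a": t.a, "b": t.b, "c": t.c, "d": t.d}
            for label, t in strata
        ]
    ).to_csv(path, sep="\t", index=False)


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    doc = {
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "n_variants": config.n_variants,
        "maf_range": list(config.maf_range),
        "planted_effects": {int(k): float(v) for k, v in config.planted_effects.items()},
        "covariate_effects": dict(config.covariate_effects),
        "gxe_effects": {f"{i}:{name}": float(v) for (i, name), v in config.gxe_effects.items()},
        "missing_rate": config.missing_rate,
        "seed": config.seed,
        "strata_design": [
            {"label": s.label, "contributes": s.contributes, "n": s.n}
            for s in config.strata_design
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text())
    gxe = {}
    for key, v in (doc.get("gxe_effects") or {}).items():
        i, name = str(key).split(":", 1)
        gxe[(int(i), name)] = float(v)
    return SimulationConfig(
        n_cases=int(doc["n_cases"]),
        n_controls=int(doc["n_controls"]),
        n_variants=int(doc["n_variants"]),
        maf_range=tuple(doc.get("maf_range", (1e-4, 0.01))),
        planted_effects={int(k): float(v) for k, v in (doc.get("planted_effects") or {}).items()},
        covariate_effects=dict(doc.get("covariate_effects") or {}),
        gxe_effects=gxe,
        missing_rate=float(doc.get("missing_rate", 0.02)),
        seed=int(doc.get("seed", 0)),
        strata_design=tuple(
            StratumSpec(str(s["label"]), str(s["contributes"]), int(s["n"]))
            for s in (doc.get("strata_design") or [])
        ),
    )
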