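"""Discovery and validation stage orchestration.

``run_discovery`` chains call/sample QC, the filtering cascade, carrier
association with FDR, the dose-effect analysis and gene-burden tests over a
cohort, emitting TSV artifacts plus a JSON run manifest with per-step
survivor counts.  ``run_validation`` pools per-candidate carrier strata and
joins the result to the gene-prioritization ranking, producing a
validation-summary table; candidates with no strata are reported as
``not_covered`` rather than failing.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assoc import CarrierTable, bh_fdr, carrier_counts, dose_effect_groups, fisher_assoc
from .burden import exome_scan
from .meta import Stratum2x2, aggregate_freq, ivw_meta, stratum_log_or
from .prioritize import ConstraintRecord, rank_candidates
from .qc import QcThresholds, call_qc, filter_cascade, sample_qc
from .types import CohortDataset, VariantRecord


@dataclass
class PipelineConfig:
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    n_perm: int = 2000
    seed: int = 0
    include_array_strata: bool = False
    masks: Sequence[tuple[str, int, int]] | None = None
    out_dir: Path | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_discovery(dataset: CohortDataset, config: PipelineConfig) -> dict:
    """QC -> filter cascade -> single-variant association (+BH-FDR) ->
    dose-effect -> gene burden.  Returns a report dict; writes artifacts
    when ``config.out_dir`` is set (partial outputs are removed if a stage
    fails)."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        report: dict = {"seed": config.seed, "version": __version__}
        stage = "call_qc"
        dataset, call_report = call_qc(dataset, config.thresholds, config.masks)
        report["call_qc"] = call_report.__dict__

        stage = "sample_qc"
        dataset, exclusions = sample_qc(dataset, config.thresholds)
        report["sample_qc"] = {
            "n_excluded": len(exclusions),
            "exclusions": [(e.sample_id, e.reason) for e in exclusions],
        }

        stage = "filter_cascade"
        candidates, cascade = filter_cascade(dataset.variants, config.thresholds)
        report["filter_cascade"] = cascade.as_dict()
        candidate_keys = [v.key for v in candidates]

        stage = "single_variant"
        rows = []
        for key in candidate_keys:
            t = carrier_counts(dataset, key)
            if t.n_cases == 0 or t.n_controls == 0 or (t.a == 0 and t.c == 0):
                continue
            res = fisher_assoc(t)
            rows.append(
                {
                    "variant_id": key,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "or": res.or_point,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "direction": res.direction,
                }
            )
        assoc_df = pd.DataFrame(rows)
        if not assoc_df.empty:
            assoc_df["q"] = bh_fdr(assoc_df["p"].tolist())
        report["single_variant"] = {"n_tested": len(assoc_df)}

        stage = "dose_effect"
        if not assoc_df.empty:
            risk = assoc_df.loc[assoc_df["or"] > 1, "variant_id"].tolist()
            prot = assoc_df.loc[assoc_df["or"] < 1, "variant_id"].tolist()
            dose = dose_effect_groups(dataset, risk, prot)
            report["dose_effect"] = {
                "n_groups": len(dose.groups),
                "trend_z": dose.trend_z,
                "trend_p": dose.trend_p,
            }
        else:
            dose = None
            report["dose_effect"] = {"n_groups": 0}

        stage = "gene_burden"
        gene_map: dict[str, list[str]] = {}
        for v in candidates:
            gene_map.setdefault(v.gene, []).append(v.key)
        burden_df = (
            exome_scan(dataset, gene_map, n_perm=config.n_perm, seed=config.seed)
            if gene_map
            else pd.DataFrame()
        )
        report["gene_burden"] = {"n_genes": len(burden_df)}

        if out_dir:
            assoc_df.to_csv(out_dir / "single_variant.tsv", sep="\t", index=False)
            burden_df.to_csv(out_dir / "gene_burden.tsv", sep="\t", index=False)
            if dose is not None:
                dose.groups.to_csv(out_dir / "dose_effect.tsv", sep="\t", index=False)
            (out_dir / "manifest.json").write_text(json.dumps(report, indent=2, default=str))
        report["assoc"] = assoc_df
        report["burden"] = burden_df
        return report
    except Exception as err:
        if out_dir:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise StageError(stage, err) from err


def run_validation(
    strata_by_candidate: Mapping[str, Sequence[tuple[str, CarrierTable]]],
    candidates: Sequence[str] | None = None,
    constraint: Sequence[ConstraintRecord] = (),
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Per-candidate IVW pooling of carrier strata plus prioritization.

    ``candidates`` lists everything that should appear in the report;
    entries with no strata come out with status ``not_covered``.
    """
    names = list(candidates) if candidates is not None else list(strata_by_candidate)
    rows = []
    for cand in names:
        pairs = strata_by_candidate.get(cand) or []
        if not pairs:
            rows.append({"candidate": cand, "status": "not_covered"})
            continue
        strata = [stratum_log_or(t, label=label) for label, t in pairs]
        res = ivw_meta(strata)
        rows.append(
            {
                "candidate": cand,
                "status": "pooled",
                "n_strata": res.n_strata,
                "case_freq_pct": res.case_freq,
                "control_freq_pct": res.control_freq,
                "or": res.or_point,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "q_het": res.q_het,
                "i2": res.i2,
            }
        )
    df = pd.DataFrame(rows)
    pooled = df["status"] == "pooled" if "status" in df else pd.Series(dtype=bool)
    if pooled.any():
        df.loc[pooled, "q"] = bh_fdr(df.loc[pooled, "p"].tolist())
    if constraint:
        ranking = rank_candidates(
            constraint,
            burden_q={r["candidate"]: r.get("q", float("inf")) for r in rows if "q" in r},
        )
        df = df.merge(
            ranking[["gene", "rank", "n_evidence_flags", "constraint_intolerant"]],
            left_on="candidate",
            right_on="gene",
            how="left",
        ).drop(columns=["gene"])
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "validation_meta.tsv", sep="\t", index=False)
    return df
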