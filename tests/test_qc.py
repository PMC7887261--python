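"""Call/sample QC boundaries and the filtering cascade, including an
independent set-logic oracle and monotonicity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrierscan.qc import (
    QcError,
    QcThresholds,
    call_qc,
    consensus_deleterious,
    filter_cascade,
    sample_qc,
)
from carrierscan.simulate import AnnotationProfile, SimulationConfig, simulate_annotations
from carrierscan.types import CLINVAR_RESCUE, TRUNCATING, VariantRecord

from conftest import make_dataset


def _variant(consequence="missense", ref_maf=0.005, n_del=0, n_tol=0, clinvar="none",
             ref="A", alt="C", flags=frozenset(), vid="v"):
    verdicts = ("deleterious",) * n_del + ("tolerated",) * n_tol
    verdicts += ("missing",) * (6 - len(verdicts))
    return VariantRecord(
        "1", 500, ref, alt, variant_id=vid, consequence=consequence,
        ref_maf=ref_maf, verdicts=verdicts, clinvar=clinvar, region_flags=flags,
    )


class TestCallQc:
    def test_het_call_below_depth_threshold_set_missing(self):
        ds = make_dataset([[1], [0]], [1, 0], depth=[[9], [50]])
        out, report = call_qc(ds, QcThresholds(min_call_rate=0.0))
        assert out.genotypes[0, 0] == -1
        assert report.calls_failed_depth == 1

    def test_allele_balance_boundary_inclusive(self):
        ds = make_dataset([[1], [1]], [1, 0], allele_balance=[[0.2], [0.19]])
        out, _ = call_qc(ds, QcThresholds(min_call_rate=0.0))
        assert out.genotypes[0, 0] == 1  # AB exactly 0.2 retained
        assert out.genotypes[1, 0] == -1

    def test_quality_boundary_inclusive(self):
        ds = make_dataset([[2], [2]], [1, 0], quality=[[20.0], [19.9]])
        out, _ = call_qc(ds, QcThresholds(min_call_rate=0.0))
        assert out.genotypes[0, 0] == 2
        assert out.genotypes[1, 0] == -1

    def test_call_rate_below_threshold_removes_variant(self):
        # 100 samples, 16 missing calls -> 84% call rate < 85%
        geno = np.zeros((100, 1), dtype=np.int8)
        geno[:16, 0] = -1
        ds = make_dataset(geno, [1] * 50 + [0] * 50)
        out, report = call_qc(ds, QcThresholds())
        assert out.n_variants == 0
        assert report.variants_failed_call_rate == 1

    def test_mask_overlap_and_region_flags_remove_variants(self):
        variants = [
            VariantRecord("1", 150, "A", "C", variant_id="in_mask"),
            VariantRecord("1", 500, "A", "C", variant_id="flagged",
                          region_flags=frozenset({"low_complexity"})),
            VariantRecord("2", 150, "A", "C", variant_id="kept"),
        ]
        ds = make_dataset(np.zeros((4, 3), dtype=np.int8), [1, 1, 0, 0], variants=variants)
        out, report = call_qc(ds, QcThresholds(), masks=[("1", 100, 200)])
        assert out.variant_keys == ["kept"]
        assert report.variants_in_mask == 1 and report.variants_region_flagged == 1

    def test_missing_metadata_raises_named_error(self):
        ds = make_dataset([[0], [0]], [1, 0])
        ds.depth = None
        with pytest.raises(QcError, match="depth"):
            call_qc(ds, QcThresholds())

    def test_only_change_is_to_missing(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
        ds = make_dataset(geno, rng.integers(0, 2, 30),
                          quality=rng.normal(30, 15, (30, 5)))
        out, _ = call_qc(ds, QcThresholds(min_call_rate=0.0))
        changed = out.genotypes != geno
        assert np.all(out.genotypes[changed] == -1)


class TestSampleQc:
    def test_low_completion_excluded(self):
        geno = np.zeros((3, 100), dtype=np.int8)
        geno[0, :6] = -1  # 94% completion
        geno[1, 0] = 1    # break up IBS identity with sample 2
        ds = make_dataset(geno, [1, 1, 0])
        out, exclusions = sample_qc(ds, QcThresholds())
        assert [(e.sample_id, e.reason) for e in exclusions] == [("s0", "completion")]
        assert out.n_samples == 2

    def test_one_of_a_clone_pair_excluded(self):
        geno = np.array([[1, 1, 0, 1], [1, 1, 0, 1], [0, 0, 1, 0]], dtype=np.int8)
        ds = make_dataset(geno, [1, 1, 0])
        out, exclusions = sample_qc(ds, QcThresholds(min_ibs_sites=1))
        related = [e for e in exclusions if e.reason == "relatedness"]
        assert len(related) == 1
        assert out.n_samples == 2

    def test_identical_het_rates_no_het_exclusions(self):
        geno = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.int8)
        ds = make_dataset(geno, [1, 1, 0, 0])
        _, exclusions = sample_qc(ds, QcThresholds(max_ibs=1.0, min_het_sites=1))
        assert not any(e.reason == "heterozygosity" for e in exclusions)

    def test_het_rate_outlier_excluded_on_large_panel(self):
        rng = np.random.default_rng(1)
        geno = (rng.random((20, 60)) < 0.3).astype(np.int8)
        geno[0] = 1  # het at every site: extreme outlier
        ds = make_dataset(geno, [1] * 10 + [0] * 10)
        _, exclusions = sample_qc(ds, QcThresholds(max_ibs=1.0, min_het_sites=50))
        assert ("s0", "heterozygosity") in [(e.sample_id, e.reason) for e in exclusions]

    def test_duplicate_ids_rejected(self):
        ds = make_dataset([[0], [0]], [1, 0])
        ds.samples.loc[1, "sample_id"] = "s0"
        with pytest.raises(QcError, match="duplicate"):
            sample_qc(ds, QcThresholds())

    def test_sex_discordance_from_x_heterozygosity(self):
        variants = [VariantRecord("X", 100 * (j + 1), "A", "C", variant_id=f"x{j}")
                    for j in range(10)]
        # sample 0: all het on X (female-like); sample 1: all hom
        geno = np.vstack([np.ones(10), np.zeros(10), np.zeros(10)]).astype(np.int8)
        ds = make_dataset(geno, [1, 0, 0], variants=variants)
        _, exclusions = sample_qc(
            ds, QcThresholds(max_ibs=1.0),
            reported_sex={"s0": "male", "s1": "male", "s2": "male"},
        )
        assert [(e.sample_id, e.reason) for e in exclusions] == [("s0", "sex_discordance")]


class TestConsensus:
    @pytest.mark.parametrize(
        "consequence,n_del,n_tol,expected",
        [
            ("missense", 4, 2, True),       # 4/6 tools
            ("missense", 3, 0, False),      # 3 deleterious / 3 missing
            ("missense", 5, 1, True),
            ("missense", 3, 3, False),
            ("frameshift", 0, 6, True),     # truncating override
            ("stop_gain", 0, 0, True),
            ("splice_donor", 1, 5, True),
        ],
    )
    def test_vote_counting_and_truncating_override(self, consequence, n_del, n_tol, expected):
        ref, alt = ("AA", "A") if consequence == "frameshift" else ("A", "C")
        v = _variant(consequence, n_del=n_del, n_tol=n_tol, ref=ref, alt=alt)
        assert consensus_deleterious(v, QcThresholds()) is expected


class TestCascade:
    def test_rare_deleterious_missense_retained(self):
        kept, _ = filter_cascade([_variant(ref_maf=0.005, n_del=5, n_tol=1)])
        assert len(kept) == 1

    def test_common_clinvar_pathogenic_still_removed(self):
        # rescue applies only to variants passing the rarity step
        kept, _ = filter_cascade([_variant(ref_maf=0.02, n_del=6, clinvar="pathogenic")])
        assert kept == []

    def test_rare_nondeleterious_vus_rescued(self):
        kept, report = filter_cascade([_variant(ref_maf=0.005, n_del=0, n_tol=6, clinvar="vus")])
        assert len(kept) == 1
        assert report.clinvar_rescued == 1

    def test_long_indel_excluded_unless_rescued(self):
        v = VariantRecord("1", 10, "A" * 26, "A", variant_id="del25",
                          consequence="frameshift", ref_maf=0.001)
        kept, _ = filter_cascade([v])
        assert kept == []

    def test_missing_ref_maf_is_an_error(self):
        v = VariantRecord("1", 10, "A", "C", variant_id="nomaf", consequence="missense")
        with pytest.raises(QcError, match="reference MAF"):
            filter_cascade([v])

    def test_idempotence(self):
        cfg = SimulationConfig(n_variants=300, seed=21)
        profiles = {i: ["deleterious_missense", "truncating", "benign_missense",
                        "regulatory", "neutral"][i % 5] for i in range(300)}
        variants = simulate_annotations(cfg, profiles)
        once, _ = filter_cascade(variants)
        twice, _ = filter_cascade(once)
        assert [v.key for v in once] == [v.key for v in twice]

    def test_monotonicity_in_thresholds(self):
        cfg = SimulationConfig(n_variants=400, maf_range=(1e-4, 0.05), seed=22)
        profiles = {i: ["deleterious_missense", "truncating", "benign_missense",
                        "regulatory", "neutral"][i % 5] for i in range(400)}
        variants = simulate_annotations(cfg, profiles)
        base, _ = filter_cascade(variants, QcThresholds())
        looser_maf, _ = filter_cascade(variants, QcThresholds(max_ref_maf=0.03))
        fewer_votes, _ = filter_cascade(variants, QcThresholds(min_deleterious_votes=2))
        assert {v.key for v in base} <= {v.key for v in looser_maf}
        assert {v.key for v in base} <= {v.key for v in fewer_votes}

    @settings(max_examples=30, deadline=None)
    @given(
        maf=st.floats(1e-5, 0.05),
        n_del=st.integers(0, 6),
        consequence=st.sampled_from(
            ["missense", "frameshift", "stop_gain", "utr3", "inframe_indel", "other"]
        ),
        clinvar=st.sampled_from(["none", "vus", "pathogenic", "benign_or_likely_benign"]),
    )
    def test_membership_matches_rule_definition(self, maf, n_del, consequence, clinvar):
        """Cascade membership of an arbitrary variant equals the direct
        boolean statement of its three steps plus rescue."""
        ref, alt = ("AAA", "A") if consequence in ("frameshift", "inframe_indel") else ("A", "C")
        v = _variant(consequence, ref_maf=maf, n_del=n_del, n_tol=6 - n_del,
                     clinvar=clinvar, ref=ref, alt=alt)
        kept, _ = filter_cascade([v])
        th = QcThresholds()
        step1 = maf < th.max_ref_maf
        step2 = (
            consequence in ({"missense", "utr3", "utr5"} | TRUNCATING)
            and abs(len(ref) - len(alt)) <= th.max_indel_len
        )
        step3 = consequence in TRUNCATING or n_del >= th.min_deleterious_votes
        expected = step1 and ((step2 and step3) or clinvar in CLINVAR_RESCUE)
        assert (len(kept) == 1) == expected
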