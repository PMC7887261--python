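"""Gene-burden tests: pattern collapsing, KBAC statistic/permutation
(against exhaustive label enumeration), CMC arithmetic and the scan."""

import itertools

import numpy as np
import pytest
from scipy import stats

from carrierscan.burden import (
    GenotypePattern,
    cmc_test,
    collapse_patterns,
    exome_scan,
    kbac_statistic,
    kbac_test,
)
from carrierscan.assoc import CarrierTable, fisher_assoc
from carrierscan.simulate import SimulationConfig, simulate_cohort

from conftest import make_dataset


def exhaustive_kbac_p(geno, n_case):
    """Independent oracle: KBAC one-sided p by enumerating every
    case-labeling of the samples (weights from scipy's hypergeometric CDF,
    statistic written directly from its definition)."""
    N = geno.shape[0]
    n_control = N - n_case
    keys = sorted({tuple(r) for r in np.asarray(geno) if any(r)})
    pid = [keys.index(tuple(r)) if any(r) else -1 for r in np.asarray(geno)]

    def stat(case_set):
        xs = np.zeros(len(keys))
        ns = np.zeros(len(keys))
        for s, p in enumerate(pid):
            if p >= 0:
                ns[p] += 1
                xs[p] += s in case_set
        w = stats.hypergeom.cdf(xs, N, n_case, ns)
        return float((w * (xs / n_case - (ns - xs) / n_control)).sum())

    obs = stat(set(range(n_case)))
    hits = total = 0
    for comb in itertools.combinations(range(N), n_case):
        total += 1
        hits += stat(set(comb)) >= obs - 1e-12
    return obs, hits / total


class TestCollapse:
    def test_single_site_collapse(self):
        geno = [[1], [1], [1], [1], [0], [0]]
        ds = make_dataset(geno, [1, 1, 1, 0, 0, 0])
        [p] = collapse_patterns(ds, [0])
        assert (p.n_total, p.n_case, p.n_control) == (4, 3, 1)

    def test_disjoint_carriers_make_two_patterns(self, tiny_dataset):
        pats = collapse_patterns(tiny_dataset, ["v0", "v1"])
        assert len(pats) == 2

    def test_empty_variant_list_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="empty"):
            collapse_patterns(tiny_dataset, [])

    def test_sample_missing_any_call_dropped(self):
        geno = [[1, -1], [1, 0], [0, 0], [0, 0]]
        ds = make_dataset(geno, [1, 1, 0, 0])
        [p] = collapse_patterns(ds, [0, 1])
        assert p.n_total == 1  # sample 0 dropped listwise

    def test_pattern_count_matches_set_dedup_oracle(self):
        rng = np.random.default_rng(5)
        geno = rng.binomial(1, 0.15, size=(60, 9)).astype(np.int8)
        ds = make_dataset(geno, rng.integers(0, 2, 60))
        pats = collapse_patterns(ds, list(range(9)))
        brute = {tuple(r) for r in geno if any(r)}
        assert len(pats) == len(brute)
        assert sum(p.n_total for p in pats) == sum(1 for r in geno if any(r))

    def test_all_reference_pattern_rejected(self):
        with pytest.raises(ValueError, match="all-reference"):
            GenotypePattern((0, 0), 1, 1, 0)


class TestKbac:
    def test_hand_worked_tiny_instance(self):
        """4 samples (2 cases), one pattern carried by one case:
        w = P(X<=1) = 1 for X~Hypergeom(4,2,1), statistic = 0.5, and 3 of
        the 6 labelings reach the observed statistic."""
        geno = np.array([[1], [0], [0], [0]], dtype=np.int8)
        obs, p_exact = exhaustive_kbac_p(geno, 2)
        assert obs == pytest.approx(0.5)
        assert p_exact == pytest.approx(0.5)
        pats = [GenotypePattern((1,), 1, 1, 0)]
        stat, p_mc = kbac_test(pats, 2, 2, n_perm=4000, seed=1, early_stop_p=None)
        assert stat == pytest.approx(0.5)
        assert abs(p_mc - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_balanced_pattern_gives_zero_statistic(self):
        pats = [GenotypePattern((1,), 2, 1, 1)]
        stat, _ = kbac_test(pats, 5, 5, n_perm=200, seed=0)
        assert stat == pytest.approx(0.0)

    def test_weights_bounded_and_reorder_invariant(self):
        pats = [
            GenotypePattern((1, 0), 3, 2, 1),
            GenotypePattern((0, 1), 2, 2, 0),
            GenotypePattern((1, 1), 1, 0, 1),
        ]
        counts = np.array([p.n_case for p in pats])
        totals = np.array([p.n_total for p in pats])
        s1 = kbac_statistic(counts, totals, 6, 6)
        s2 = kbac_statistic(counts[::-1].copy(), totals[::-1].copy(), 6, 6)
        assert s1 == pytest.approx(s2)
        w = [stats.hypergeom.cdf(p.n_case, 12, 6, p.n_total) for p in pats]
        assert all(0.0 <= wi <= 1.0 for wi in w)

    def test_no_patterns_is_defined_null(self):
        assert kbac_test([], 5, 5, n_perm=200, seed=0) == (0.0, 1.0)

    def test_n_perm_floor(self):
        with pytest.raises(ValueError):
            kbac_test([], 5, 5, n_perm=10, seed=0)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_monte_carlo_matches_exhaustive_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(6, 13))
        n_case = N // 2
        geno = rng.binomial(1, 0.3, size=(N, 3)).astype(np.int8)
        if not geno.any():
            geno[0, 0] = 1
        obs, p_exact = exhaustive_kbac_p(geno, n_case)
        ds = make_dataset(geno, [1] * n_case + [0] * (N - n_case))
        pats = collapse_patterns(ds, [0, 1, 2])
        stat, p_mc = kbac_test(pats, n_case, N - n_case, n_perm=5000, seed=99,
                               early_stop_p=None)
        assert stat == pytest.approx(obs, abs=1e-10)
        assert abs(p_mc - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 5000) + 1e-3

    def test_deterministic_under_seed(self):
        pats = [GenotypePattern((1,), 4, 3, 1), GenotypePattern((2,), 2, 0, 2)]
        r1 = kbac_test(pats, 10, 10, n_perm=1000, seed=42)
        r2 = kbac_test(pats, 10, 10, n_perm=1000, seed=42)
        assert r1 == r2

    def test_early_stop_reports_p_above_threshold(self):
        pats = [GenotypePattern((1,), 2, 1, 1)]  # null-ish: stat 0
        _, p = kbac_test(pats, 20, 20, n_perm=10000, seed=0, early_stop_p=0.1,
                         batch_size=200)
        assert p >= 0.1


class TestCmc:
    def test_crude_or_matches_hand_arithmetic_protective(self):
        # 3/1045 case carriers vs 12/885 control carriers
        geno = np.zeros((1930, 1), dtype=np.int8)
        geno[:3] = 1
        geno[1045:1057] = 1
        ds = make_dataset(geno, [1] * 1045 + [0] * 885)
        out = cmc_test(ds, [0])
        assert out["cmc_or"] == pytest.approx((3 * 873) / (1042 * 12), abs=1e-4)
        assert out["cmc_or"] == pytest.approx(0.2094, abs=1e-4)

    def test_crude_or_second_hand_value(self):
        geno = np.zeros((1930, 1), dtype=np.int8)
        geno[:10] = 1
        geno[1045:1072] = 1
        ds = make_dataset(geno, [1] * 1045 + [0] * 885)
        out = cmc_test(ds, [0])
        assert out["cmc_or"] == pytest.approx(0.3070, abs=1e-4)

    def test_degenerate_when_no_carriers(self):
        ds = make_dataset(np.zeros((6, 1), dtype=np.int8), [1, 1, 1, 0, 0, 0])
        out = cmc_test(ds, [0])
        assert out["degenerate"]
        assert np.isnan(out["cmc_or"])

    def test_crude_or_equals_fisher_on_collapsed_table(self):
        rng = np.random.default_rng(8)
        geno = rng.binomial(1, 0.1, size=(200, 4)).astype(np.int8)
        ds = make_dataset(geno, rng.integers(0, 2, 200))
        out = cmc_test(ds, [0, 1, 2, 3])
        ref = fisher_assoc(out["table"])
        assert out["cmc_or"] == pytest.approx(ref.or_point, rel=1e-12)
        assert out["cmc_p"] == pytest.approx(ref.p, rel=1e-12)

    def test_adjusted_or_reported_alongside(self):
        cfg = SimulationConfig(
            n_cases=800, n_controls=800, n_variants=3, maf_range=(0.03, 0.06),
            planted_effects={0: 0.7}, missing_rate=0.0, seed=12,
        )
        ds = simulate_cohort(cfg)
        out = cmc_test(ds, [0, 1, 2], adjust=["age", "sex"])
        assert out["cmc_or_adjusted"] is not None
        assert out["cmc_or"] > 0  # crude retained too


class TestScan:
    def test_single_gene_q_equals_p(self):
        geno = np.array([[1], [0], [1], [0], [0], [0]], dtype=np.int8)
        ds = make_dataset(geno, [1, 1, 1, 0, 0, 0])
        df = exome_scan(ds, {"G1": [0]}, n_perm=200, seed=0)
        assert df.loc[0, "cmc_q"] == pytest.approx(df.loc[0, "cmc_p"])
        assert df.loc[0, "kbac_q"] == pytest.approx(df.loc[0, "kbac_p"])

    def test_permuted_phenotypes_give_no_discoveries(self):
        cfg = SimulationConfig(
            n_cases=250, n_controls=250, n_variants=20, maf_range=(0.02, 0.05),
            missing_rate=0.0, seed=77,
        )
        ds = simulate_cohort(cfg)
        gene_map = {f"G{k}": [4 * k, 4 * k + 1, 4 * k + 2, 4 * k + 3] for k in range(5)}
        df = exome_scan(ds, gene_map, n_perm=500, seed=7)
        assert (df["cmc_q"].dropna() > 0.05).all()
        assert (df["kbac_q"] > 0.05).all()

    def test_empty_gene_map_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            exome_scan(tiny_dataset, {}, n_perm=200, seed=0)
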