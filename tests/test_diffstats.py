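"""Two-sample per-SNP statistics: Z, chi-square, Haldane-Woolf OR, corrections.

The multiplicity corrections are cross-checked against independent
brute-force implementations written here: Bonferroni/Hochberg/BH as direct
step-up recursions, Hommel as full closed testing over all subsets with
Simes local tests.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from statsmodels.stats.proportion import proportions_ztest

from scxci.aggregate import summarize_positions, filter_for_skewing
from scxci.diffstats import (
    ADJUST_METHODS,
    ContingencyTable2x2,
    adjust_pvalues,
    build_table,
    chi_square_2x2,
    compare_samples,
    direction_tally,
    haldane_woolf_or,
    two_proportion_z,
)
from scxci.simulate import SimulationConfig, simulate
from tests.conftest import make_summary


def random_tables(rng, n, low=0, high=40):
    for _ in range(n):
        a, b, c, d = (int(x) for x in rng.integers(low, high, size=4))
        yield ContingencyTable2x2(a, b, c, d)


# ---------------------------------------------------------------- oracles

def brute_bonferroni(p):
    return [min(1.0, len(p) * x) for x in p]


def brute_hochberg(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def brute_bh(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, m * p[i] / (rank + 1))
        adj[i] = min(1.0, running)
    return adj


def brute_hommel(p):
    """Closed testing with Simes local tests over every subset (m small)."""
    m = len(p)
    adj = []
    for i in range(m):
        worst = 0.0
        for size in range(1, m + 1):
            for subset in itertools.combinations(range(m), size):
                if i not in subset:
                    continue
                ps = sorted(p[j] for j in subset)
                simes = min(len(ps) * q / (k + 1) for k, q in enumerate(ps))
                worst = max(worst, simes)
        adj.append(min(1.0, worst))
    return adj


# ----------------------------------------------------------------- tests

class TestBuildTable:
    def test_major_first_per_sample(self):
        t = build_table(make_summary(1, 8, 2), make_summary(1, 3, 7))
        assert t.rows == ((8, 2), (7, 3))

    def test_tie_keeps_input_order(self):
        t = build_table(make_summary(1, 5, 5), make_summary(1, 6, 4))
        assert (t.a, t.b) == (5, 5)

    def test_haplotype_orientation_preserves_labels(self):
        t = build_table(make_summary(1, 2, 8), make_summary(1, 3, 7),
                        orientation="haplotype_labels")
        assert t.rows == ((2, 8), (3, 7))

    def test_rows_conserve_sample_totals(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            x = [int(v) for v in rng.integers(1, 40, size=4)]
            nf, gd = make_summary(1, x[0], x[1]), make_summary(1, x[2], x[3])
            t = build_table(nf, gd)
            assert t.a + t.b == x[0] + x[1] and t.c + t.d == x[2] + x[3]

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            build_table(make_summary(1, 0, 0, freq=5), make_summary(1, 3, 3))

    def test_position_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_table(make_summary(1, 3, 3), make_summary(2, 3, 3))


class TestTwoProportionZ:
    def test_identical_rows_give_null(self):
        assert two_proportion_z(ContingencyTable2x2(8, 2, 8, 2)) == (0.0, 1.0)

    def test_matches_pooled_reference(self):
        t = ContingencyTable2x2(80, 20, 50, 50)
        z, p = two_proportion_z(t)
        z_ref, p_ref = proportions_ztest([80, 50], [100, 100])
        assert z == pytest.approx(z_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_antisymmetric_under_row_swap(self):
        rng = np.random.default_rng(43)
        for t in random_tables(rng, 50, low=1):
            z, _ = two_proportion_z(t)
            z_swapped, _ = two_proportion_z(t.swapped_rows())
            assert z == pytest.approx(-z_swapped, abs=1e-12)

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_z(ContingencyTable2x2(5, 0, 7, 0)) == (0.0, 1.0)
        assert two_proportion_z(ContingencyTable2x2(0, 5, 0, 7)) == (0.0, 1.0)


class TestChiSquare:
    def test_identical_rows(self):
        chi2, p = chi_square_2x2(ContingencyTable2x2(8, 2, 8, 2))
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_equals_z_squared_on_random_tables(self):
        rng = np.random.default_rng(47)
        checked = 0
        for t in random_tables(rng, 1000, low=0, high=60):
            margins_ok = (t.a + t.b) and (t.c + t.d) and (t.a + t.c) and (t.b + t.d)
            if not margins_ok:
                continue
            z, p_z = two_proportion_z(t)
            chi2, p_chi2 = chi_square_2x2(t)
            assert chi2 == pytest.approx(z * z, abs=1e-9)
            assert p_chi2 == pytest.approx(p_z, abs=1e-9)
            checked += 1
        assert checked > 900

    def test_matches_textbook_expected_counts(self):
        t = ContingencyTable2x2(80, 20, 50, 50)
        chi2, _ = chi_square_2x2(t)
        # independent sum((O-E)^2 / E)
        obs = [[80, 20], [50, 50]]
        n = 200
        expected = 0.0
        for i in range(2):
            for j in range(2):
                e = sum(obs[i]) * (obs[0][j] + obs[1][j]) / n
                expected += (obs[i][j] - e) ** 2 / e
        assert chi2 == pytest.approx(expected, abs=1e-9)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable2x2(5, 0, 7, 0))


class TestHaldaneWoolfOR:
    def test_symmetric_table_gives_unity(self):
        or_value, lo, hi = haldane_woolf_or(ContingencyTable2x2(10, 10, 10, 10))
        assert or_value == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cells_stay_finite(self):
        or_value, lo, hi = haldane_woolf_or(ContingencyTable2x2(0, 10, 10, 0))
        assert or_value == pytest.approx((0.5 * 0.5) / (10.5 * 10.5))
        assert 0 < lo <= or_value <= hi < math.inf

    def test_row_swap_inverts_odds_ratio(self):
        rng = np.random.default_rng(53)
        for t in random_tables(rng, 100):
            or_value, lo, hi = haldane_woolf_or(t)
            or_swapped, lo_s, hi_s = haldane_woolf_or(t.swapped_rows())
            assert or_swapped == pytest.approx(1.0 / or_value, rel=1e-12)
            assert lo_s == pytest.approx(1.0 / hi, rel=1e-12)

    def test_ci_width_matches_woolf_se(self):
        t = ContingencyTable2x2(12, 5, 7, 20)
        or_value, lo, hi = haldane_woolf_or(t, alpha=0.05)
        se = math.sqrt(sum(1.0 / (x + 0.5) for x in (12, 5, 7, 20)))
        assert math.log(hi) - math.log(lo) == pytest.approx(2 * 1.959963984540054 * se)


class TestAdjustPvalues:
    def test_bonferroni_small_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03], "bonferroni") == pytest.approx(
            [0.03, 0.06, 0.09]
        )

    @pytest.mark.parametrize("method,oracle", [
        ("bonferroni", brute_bonferroni),
        ("hochberg", brute_hochberg),
        ("fdr", brute_bh),
        ("hommel", brute_hommel),
    ])
    def test_matches_independent_oracle(self, method, oracle):
        rng = np.random.default_rng(59)
        for _ in range(20):
            m = int(rng.integers(1, 8))
            p = [float(x) for x in rng.uniform(0, 1, size=m)]
            assert adjust_pvalues(p, method) == pytest.approx(oracle(p), abs=1e-9)

    def test_dominance_relations_and_monotonicity(self):
        rng = np.random.default_rng(61)
        for _ in range(30):
            p = [float(x) for x in rng.uniform(0, 1, size=int(rng.integers(1, 15)))]
            bonf = adjust_pvalues(p, "bonferroni")
            hoch = adjust_pvalues(p, "hochberg")
            homm = adjust_pvalues(p, "hommel")
            fdr = adjust_pvalues(p, "fdr")
            for raw, b, h, hm, f in zip(p, bonf, hoch, homm, fdr):
                assert b >= h - 1e-12 >= 0
                assert h >= hm - 1e-12
                assert min(b, h, hm, f) >= raw - 1e-12

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(67)
        p = [float(x) for x in rng.uniform(0, 1, size=9)]
        perm = list(rng.permutation(9))
        for method in ADJUST_METHODS:
            direct = adjust_pvalues([p[i] for i in perm], method)
            ref = adjust_pvalues(p, method)
            assert direct == pytest.approx([ref[i] for i in perm], abs=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bonferroni")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm-sidak-nope")


class TestCompareSamples:
    def test_disjoint_position_sets_give_empty_output(self):
        nf = [make_summary(1, 5, 5)]
        gd = [make_summary(2, 5, 5)]
        assert compare_samples(nf, gd) == []

    def test_single_shared_position_family_of_one(self):
        nf = [make_summary(7, 18, 4)]
        gd = [make_summary(7, 6, 12)]
        (c,) = compare_samples(nf, gd)
        assert c.pos == 7
        for m in ADJUST_METHODS:
            assert c.p_adj[m] == pytest.approx(c.p_z)
        assert c.direction == "case_less"  # 81.8% vs 66.7%
        assert c.ci_low <= c.or_value <= c.ci_high

    def test_direction_tally_sums_to_shared_positions(self):
        rng = np.random.default_rng(71)
        nf = [make_summary(i, 3 + int(rng.integers(0, 20)), 3 + int(rng.integers(0, 20)))
              for i in range(1, 40)]
        gd = [make_summary(i, 3 + int(rng.integers(0, 20)), 3 + int(rng.integers(0, 20)))
              for i in range(1, 40)]
        comps = compare_samples(nf, gd)
        tally = direction_tally(comps)
        assert sum(tally.values()) == len(comps) == 39

    def test_planted_skew_difference_is_detected_with_power(self):
        """FDR < 0.05 recovers strongly skew-shifted positions in most replicates.

        Each replicate simulates a balanced control and a heavily skewed case
        at deep coverage; detection power for the planted difference is
        estimated over 200 small replicates.
        """
        rng = np.random.default_rng(73)
        detected = 0
        n_rep = 200
        for _ in range(n_rep):
            # 8 null positions plus one planted difference, 60 UMIs each
            nf, gd = [], []
            for pos in range(1, 9):
                a = int(rng.binomial(60, 0.5))
                b = int(rng.binomial(60, 0.5))
                nf.append(make_summary(pos, a, 60 - a))
                gd.append(make_summary(pos, b, 60 - b))
            a = int(rng.binomial(60, 0.5))
            b = int(rng.binomial(60, 0.95))
            nf.append(make_summary(9, a, 60 - a))
            gd.append(make_summary(9, b, 60 - b))
            comps = {c.pos: c for c in compare_samples(nf, gd)}
            if comps[9].p_adj["fdr"] < 0.05:
                detected += 1
        assert detected / n_rep > 0.9

    def test_self_comparison_of_simulated_sample_is_null(self):
        records, _ = simulate(SimulationConfig(
            n_positions=60, n_cells=120, leak_rate=0.0,
            escape_rate=0.0, n_homozygous_decoys=0, seed=101,
        ))
        filtered = filter_for_skewing(summarize_positions(records))
        assert filtered, "simulation produced no filter-passing positions"
        comps = compare_samples(filtered, filtered)
        assert {c.pos for c in comps} == {s.pos for s in filtered}
        for c in comps:
            assert c.z == pytest.approx(0.0) and c.p_z == pytest.approx(1.0)
            assert c.direction == "equal"
            assert c.ci_low <= c.or_value <= c.ci_high
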