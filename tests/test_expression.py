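"""Unit and property tests for the pooled differential-expression screen."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psyscreen.expression import (
    InputError,
    StringencyGridRow,
    compute_alr,
    count_passing,
    default_permutation_designs,
    enumerate_balanced_designs,
    fdr_grid,
    fdr_percent,
    pairwise_robustness,
    robust_hits,
    select_stringency,
    two_tailed_t,
)
from psyscreen.simulate import SimulationConfig, gen_expression

from conftest import CONTROL, PUBLISHED_GRID, TREATED, make_matrix


class TestComputeAlr:
    @pytest.mark.parametrize(
        "treated, control, expected",
        [
            ([2, 2, 2, 2], [2, 2, 2, 2], 0.0),
            ([3, 3, 3, 3], [2, 2, 2, 2], 1.0),
            ([7.1, 7.3, 6.9, 7.5], [6.0, 6.2, 6.4, 5.8], 1.1),
        ],
    )
    def test_mean_difference(self, treated, control, expected):
        m = make_matrix({"p1": treated + control})
        assert compute_alr(m, TREATED, CONTROL)[0] == pytest.approx(expected)

    def test_unknown_sample_rejected(self):
        m = make_matrix({"p1": [1] * 8})
        with pytest.raises(InputError):
            compute_alr(m, ["e1", "nope"], CONTROL)

    def test_overlapping_groups_rejected(self):
        m = make_matrix({"p1": [1] * 8})
        with pytest.raises(InputError):
            compute_alr(m, TREATED, TREATED)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=8, max_size=8
        )
    )
    def test_antisymmetry(self, values):
        m = make_matrix({"p1": values})
        fwd = compute_alr(m, TREATED, CONTROL)[0]
        rev = compute_alr(m, CONTROL, TREATED)[0]
        assert fwd == pytest.approx(-rev, abs=1e-12)


class TestTwoTailedT:
    def test_identical_groups_degenerate(self):
        m = make_matrix({"p1": [5, 5, 5, 5, 5, 5, 5, 5]})
        t, p = two_tailed_t(m, TREATED, CONTROL)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_known_example(self):
        # equal-variance t for (1,2,3,4) vs (2,3,4,5): pooled var 5/3,
        # t = -1/sqrt(5/6), df = 6; tail probability frozen from the
        # t-distribution CDF at that closed-form statistic
        m = make_matrix({"p1": [1, 2, 3, 4, 2, 3, 4, 5]})
        t, p = two_tailed_t(m, TREATED, CONTROL)
        assert t[0] == pytest.approx(-1.0954451150103321, abs=1e-9)
        assert p[0] == pytest.approx(0.3153335962012299, abs=1e-9)

    def test_group_swap_negates_t_keeps_p(self, random_matrix):
        t1, p1 = two_tailed_t(random_matrix, TREATED, CONTROL)
        t2, p2 = two_tailed_t(random_matrix, CONTROL, TREATED)
        np.testing.assert_allclose(t1, -t2, atol=1e-12)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_agrees_with_reference_within_1e9(self, random_matrix):
        t, p = two_tailed_t(random_matrix, TREATED, CONTROL)
        a = random_matrix.values[TREATED].to_numpy()
        b = random_matrix.values[CONTROL].to_numpy()
        ref = stats.ttest_ind(a, b, axis=1)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-9)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-9)

    def test_welch_agrees_with_reference(self, random_matrix):
        t, p = two_tailed_t(random_matrix, TREATED, CONTROL, variant="welch")
        a = random_matrix.values[TREATED].to_numpy()
        b = random_matrix.values[CONTROL].to_numpy()
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-9)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-9)

    def test_zero_variance_unequal_means(self):
        m = make_matrix({"p1": [3, 3, 3, 3, 2, 2, 2, 2]})
        t, p = two_tailed_t(m, TREATED, CONTROL)
        assert np.isinf(t[0]) and t[0] > 0 and p[0] == 0.0

    def test_small_group_rejected(self):
        m = make_matrix({"p1": [1] * 8})
        with pytest.raises(InputError):
            two_tailed_t(m, ["e1"], CONTROL)


class TestPermutationDesigns:
    def test_printed_designs(self):
        designs = default_permutation_designs(TREATED, CONTROL)
        assert [d.label for d in designs] == ["Boot 1", "Boot 2", "Boot 3"]
        assert designs[0].side_a == frozenset({"c1", "c2", "e3", "e4"})
        assert designs[0].side_b == frozenset({"c3", "c4", "e1", "e2"})
        assert designs[1].side_a == frozenset({"c1", "c3", "e2", "e4"})
        assert designs[1].side_b == frozenset({"c2", "c4", "e1", "e3"})
        assert designs[2].side_a == frozenset({"c1", "c4", "e2", "e3"})
        assert designs[2].side_b == frozenset({"c2", "c3", "e1", "e4"})

    def test_balance_and_coverage(self):
        for d in default_permutation_designs(TREATED, CONTROL):
            assert len(d.side_a & set(TREATED)) == 2
            assert len(d.side_a & set(CONTROL)) == 2
            assert d.side_a | d.side_b == set(TREATED) | set(CONTROL)
            assert not d.side_a & d.side_b

    def test_pairwise_distinct_up_to_side_swap(self):
        designs = default_permutation_designs(TREATED, CONTROL)
        keys = {frozenset({d.side_a, d.side_b}) for d in designs}
        assert len(keys) == 3

    def test_wrong_arm_size_directs_to_enumeration(self):
        with pytest.raises(InputError, match="enumerate_balanced_designs"):
            default_permutation_designs(["e1", "e2"], CONTROL)

    def test_enumeration_yields_18_balanced_splits(self):
        designs = enumerate_balanced_designs(TREATED, CONTROL)
        assert len(designs) == 18
        keys = {frozenset({d.side_a, d.side_b}) for d in designs}
        assert len(keys) == 18
        for d in designs:
            assert len(d.side_a & set(TREATED)) == 2
            assert len(d.side_a & set(CONTROL)) == 2


class TestCountPassing:
    @pytest.mark.parametrize(
        "alr, p, thresh, expected",
        [
            ([], [], (0.585, 0.05), 0),
            ([0.6, -0.7, 0.3], [0.01, 0.04, 0.001], (0.585, 0.05), 2),
            ([0.6, -0.7, 0.3], [0.01, 0.04, 0.001], (0.0, 1.0), 3),
            ([0.585, 0.5849], [0.01, 0.01], (0.585, 0.05), 1),  # inclusive
            ([1.0], [0.05], (0.585, 0.05), 0),  # p strictly below
        ],
    )
    def test_counts(self, alr, p, thresh, expected):
        assert count_passing(np.array(alr), np.array(p), *thresh) == expected

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InputError):
            count_passing(np.zeros(3), np.zeros(2), 0.5, 0.05)


class TestFdrFormula:
    @pytest.mark.parametrize("alr, p, exp, perm, expected", PUBLISHED_GRID)
    def test_reproduces_published_column(self, alr, p, exp, perm, expected):
        row = StringencyGridRow.from_counts(alr, p, exp, perm)
        if exp == 0:
            assert math.isnan(row.fdr_percent)
        else:
            assert round(row.fdr_percent, 1) == expected

    def test_mean_all_aggregation(self):
        assert fdr_percent(74, (39, 12, 14), agg="mean_all") == pytest.approx(
            100 * (39 + 12 + 14) / 3 / 74
        )

    def test_zero_exp_count_is_nan(self):
        assert math.isnan(fdr_percent(0, (1, 2, 3)))

    def test_can_exceed_100(self):
        assert fdr_percent(1, (5, 5)) == pytest.approx(500.0)


class TestFdrGrid:
    def test_null_matrix_grid_and_monotonicity(self):
        matrix, _ = gen_expression(
            SimulationConfig(n_probes=3000, n_de=0, seed=5)
        )
        grid = fdr_grid(matrix)
        by_key = {(r.alr_thresh, r.p_thresh): r for r in grid}
        # exp_count non-increasing in alr_thresh at fixed p, and in
        # decreasing p at fixed alr
        assert (
            by_key[(0.585, 0.05)].exp_count >= by_key[(0.848, 0.05)].exp_count
        )
        assert (
            by_key[(0.585, 0.05)].exp_count >= by_key[(0.585, 0.01)].exp_count
        )
        assert (
            by_key[(0.585, 0.01)].exp_count
            >= by_key[(0.585, 0.005)].exp_count
        )
        for row in grid:
            assert len(row.perm_counts) == 3

    def test_spiked_probes_dominate_experimental_counts(self):
        matrix, truth = gen_expression(
            SimulationConfig(
                n_probes=2000, n_de=40, effect_log2=1.2, seed=11
            )
        )
        grid = fdr_grid(matrix, [(0.585, 0.05)])
        assert grid[0].exp_count > max(grid[0].perm_counts)


class TestSelectStringency:
    def _published_rows(self):
        return [
            StringencyGridRow.from_counts(a, p, e, c)
            for a, p, e, c, _ in PUBLISHED_GRID
        ]

    def test_published_grid_selects_lowest_fdr_with_yield(self):
        # the 0.0%-FDR row has one hit only and must not win
        sel = select_stringency(self._published_rows(), min_exp=10)
        assert (sel.alr_thresh, sel.p_thresh) == (0.585, 0.05)
        assert round(sel.fdr_percent, 1) == 34.5

    def test_single_row_grid(self):
        row = StringencyGridRow.from_counts(0.5, 0.05, 20, (5, 5))
        assert select_stringency([row]) is row

    def test_tie_breaks_to_larger_yield(self):
        a = StringencyGridRow.from_counts(0.5, 0.05, 40, (4, 4))
        b = StringencyGridRow.from_counts(0.8, 0.05, 20, (2, 2))
        assert select_stringency([a, b]).exp_count == 40

    def test_fallback_to_global_minimum_when_no_yield(self):
        rows = [
            StringencyGridRow.from_counts(0.5, 0.05, 2, (2, 2)),
            StringencyGridRow.from_counts(0.8, 0.05, 1, (0, 0)),
        ]
        sel = select_stringency(rows, min_exp=10)
        assert sel.exp_count == 1

    def test_all_nan_rejected(self):
        rows = [StringencyGridRow.from_counts(0.5, 0.05, 0, (0, 0))]
        with pytest.raises(InputError):
            select_stringency(rows)


class TestPairwiseRobustness:
    def test_uniform_shift_gives_full_count_zero_sd(self):
        m = make_matrix({"p1": [3, 3, 3, 3, 2, 2, 2, 2]})
        (r,) = pairwise_robustness(m)
        assert r.pairwise_count == 16
        assert r.pairwise_sd == 0.0
        assert r.direction == "up_in_treated"

    def test_flat_probe(self):
        m = make_matrix({"p1": [1] * 8})
        (r,) = pairwise_robustness(m)
        assert r.pairwise_count == 0 and r.pairwise_sd == 0.0

    def test_exhaustive_16_pair_oracle(self):
        treated = [8.0, 8.2, 7.8, 8.4]
        control = [7.0, 7.2, 7.4, 6.8]
        m = make_matrix({"p1": treated + control})
        (r,) = pairwise_robustness(m, thresh=0.585)
        diffs = [t - c for t, c in itertools.product(treated, control)]
        assert r.pairwise_count == sum(abs(d) >= 0.585 for d in diffs)
        assert r.pairwise_sd == pytest.approx(np.std(diffs, ddof=1))
        assert r.alr == pytest.approx(np.mean(diffs))

    def test_matches_bruteforce_on_random_probes(self, random_matrix):
        results = pairwise_robustness(random_matrix, thresh=0.3)
        tv = random_matrix.values[TREATED].to_numpy()
        cv = random_matrix.values[CONTROL].to_numpy()
        for i in (0, 17, 503, 999):
            diffs = [
                tv[i, a] - cv[i, b] for a in range(4) for b in range(4)
            ]
            assert results[i].pairwise_count == sum(
                abs(d) >= 0.3 for d in diffs
            )
            assert results[i].pairwise_sd == pytest.approx(
                np.std(diffs, ddof=1)
            )

    def test_empty_arm_rejected(self):
        m = make_matrix({"p1": [1] * 8})
        with pytest.raises(InputError):
            pairwise_robustness(m, treated_ids=[], control_ids=CONTROL)


class TestRobustHits:
    def test_min_count_boundary(self):
        m = make_matrix(
            {
                # 3 of 4 treated shifted: 12 big pairwise diffs
                "p_twelve": [3, 3, 3, 2, 2, 2, 2, 2],
                # 2 of 4 treated shifted: 8 big pairwise diffs
                "p_eight": [3, 3, 2, 2, 2, 2, 2, 2],
            }
        )
        results = pairwise_robustness(m)
        counts = {r.probe_id: r.pairwise_count for r in results}
        assert counts == {"p_twelve": 12, "p_eight": 8}
        kept = {r.probe_id for r in robust_hits(results, min_count=9)}
        assert kept == {"p_twelve"}
        assert {r.probe_id for r in robust_hits(results, min_count=8)} == {
            "p_twelve",
            "p_eight",
        }

    def test_ordering_most_downregulated_first(self):
        m = make_matrix(
            {
                "up": [3, 3, 3, 3, 2, 2, 2, 2],
                "down": [2, 2, 2, 2, 4, 4, 4, 4],
            }
        )
        hits = robust_hits(pairwise_robustness(m), min_count=9)
        assert [h.probe_id for h in hits] == ["down", "up"]

    def test_recovers_exactly_spiked_probes_at_low_noise(self):
        config = SimulationConfig(
            n_probes=5000,
            n_de=10,
            effect_log2=1.0,
            animal_sd=0.15,
            tech_sd=0.05,
            seed=123,
        )
        matrix, truth = gen_expression(config)
        hits = robust_hits(pairwise_robustness(matrix), min_count=9)
        assert {h.probe_id for h in hits} == truth.de_probe_ids
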