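"""Exact solvers: hand-computed values, closed forms, oracle equivalence,
symmetry-reduced programs, and the proved time bounds as properties."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from morancol.graph_core import (
    backward_graph,
    complete_graph,
    cycle_graph,
    double_star_graph,
    lollipop_graph,
    lollipop_path_length,
    random_reachable_digraph,
    star_graph,
    total_order_graph,
)
from morancol.exact_times import (
    StateCapExceeded,
    absorption_exact_classic,
    closed_form,
    colonization_exact,
    colonization_exact_bruteforce,
    double_star_exact,
    harmonic,
    lollipop_exact,
    worst_start_time,
)
from morancol.experiments import fit_loglog_slope


class TestColonizationExact:
    @pytest.mark.parametrize("graph,init,expected", [
        (backward_graph(3), {0}, 9),   # stages of length 3 and 6, by hand
        (complete_graph(2), {0}, 2),   # single stage, success prob 1/2
        (cycle_graph(6), {0}, 30),     # every stage gains with prob 1/n
    ])
    def test_hand_computed_values(self, graph, init, expected):
        res = colonization_exact(graph, init, arithmetic="rational")
        assert res.expected_modified_steps == expected

    def test_real_time_is_modified_over_n(self):
        for g in (backward_graph(7), star_graph(6), total_order_graph(5)):
            res = colonization_exact(g, {0}, arithmetic="rational")
            assert res.expected_real_time * g.n == res.expected_modified_steps
            assert res.expected_classic_steps <= res.expected_modified_steps

    def test_state_cap_refusal_names_count(self):
        with pytest.raises(StateCapExceeded, match="10"):
            colonization_exact(complete_graph(8), {0}, state_cap=10)

    def test_unreachable_init_rejected(self):
        with pytest.raises(ValueError, match="reach"):
            colonization_exact(total_order_graph(4), {2})

    def test_float_mode_matches_rational(self):
        g = star_graph(9)
        rat = colonization_exact(g, {1}, arithmetic="rational")
        flt = colonization_exact(g, {1}, arithmetic="float")
        assert flt.expected_modified_steps == pytest.approx(
            float(rat.expected_modified_steps), rel=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("graph,start", [
        (backward_graph(8), 0),
        (complete_graph(6), 0),
        (cycle_graph(7), 0),
        (star_graph(7), 1),
        (double_star_graph(3), 2),
        (total_order_graph(6), 0),
        (lollipop_graph(8), 0),
    ])
    def test_dp_equals_bruteforce_bit_exact(self, graph, start):
        dp = colonization_exact(graph, {start}, arithmetic="rational")
        bf = colonization_exact_bruteforce(graph, {start}, arithmetic="rational")
        assert dp.expected_modified_steps == bf.expected_modified_steps
        assert dp.expected_classic_steps == bf.expected_classic_steps

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_random_digraphs_property(self, seed):
        g = random_reachable_digraph(6, 0.4, seed=seed)
        dp = colonization_exact(g, {0}, arithmetic="rational")
        bf = colonization_exact_bruteforce(g, {0}, arithmetic="rational")
        assert dp.expected_modified_steps == bf.expected_modified_steps
        n = g.n
        # proved bounds: n H(n-1) <= T <= n^3/2 - n^2/2
        assert dp.expected_modified_steps >= n * harmonic(n - 1, exact=True)
        assert dp.expected_modified_steps <= Fraction(n**3 - n**2, 2)


class TestClosedForms:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_backward_formula(self, n):
        res = colonization_exact(backward_graph(n), {0}, arithmetic="rational")
        assert res.expected_modified_steps == closed_form("backward", n, exact=True)
        assert closed_form("backward", n, exact=True) == Fraction(n**2 * (n - 1), 2)

    @pytest.mark.parametrize("family,start", [
        ("complete", 0), ("cycle", 0), ("star", 1),
    ])
    @pytest.mark.parametrize("n", range(3, 11))
    def test_stage_sums_match_solver(self, family, start, n):
        builders = {"complete": complete_graph, "cycle": cycle_graph,
                    "star": star_graph}
        res = colonization_exact(builders[family](n), {start},
                                 arithmetic="rational")
        assert res.expected_modified_steps == closed_form(family, n, exact=True)

    def test_c3_equals_k3(self):
        assert closed_form("cycle", 3) == closed_form("complete", 3) == 6

    def test_star_3_value(self):
        assert closed_form("star", 3, exact=True) == 9

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="closed form"):
            closed_form("lollipop", 10)


class TestAbsorptionClassic:
    @pytest.mark.parametrize("n", [2, 3])
    def test_neutral_fixation_probability_is_one_over_n(self, n):
        sol = absorption_exact_classic(complete_graph(n), {0}, r=1.0)
        assert sol.fixation_probability == pytest.approx(1 / n, abs=1e-12)

    def test_lollipop_path_start_always_fixes(self):
        # node 0 has no incoming edges: mutants there cannot be overwritten
        sol = absorption_exact_classic(lollipop_graph(9), {0}, r=4.0)
        assert sol.fixation_probability == pytest.approx(1.0, abs=1e-9)
        assert sol.expected_classic_steps > 0

    def test_size_and_fitness_guards(self):
        with pytest.raises(ValueError, match="n <= 12"):
            absorption_exact_classic(complete_graph(13), {0}, r=2.0)
        with pytest.raises(ValueError, match="positive"):
            absorption_exact_classic(complete_graph(3), {0}, r=-1.0)


class TestDoubleStar:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_reduced_program_matches_full_dp(self, k):
        g = double_star_graph(k)
        ds = double_star_exact(k, arithmetic="rational")
        center = colonization_exact(g, {0}, arithmetic="rational")
        leaf = colonization_exact(g, {2}, arithmetic="rational")
        assert ds.first.expected_modified_steps == center.expected_modified_steps
        assert ds.second.expected_modified_steps == leaf.expected_modified_steps
        assert ds.second.expected_classic_steps == leaf.expected_classic_steps

    def test_monotone_in_k_and_below_star(self):
        prev = 0.0
        for k in range(2, 51):
            t = double_star_exact(k).second.expected_modified_steps
            assert t > prev
            prev = t
        assert prev < closed_form("star", 100)


class TestLollipop:
    def test_reduced_program_matches_full_dp(self):
        n, p = 9, lollipop_path_length(9)
        g = lollipop_graph(n)
        lp = lollipop_exact(n, arithmetic="rational")
        a = colonization_exact(g, {0}, arithmetic="rational")
        b = colonization_exact(g, {0} | set(range(p, n)), arithmetic="rational")
        assert lp.first.expected_modified_steps == a.expected_modified_steps
        assert lp.first.expected_classic_steps == a.expected_classic_steps
        assert lp.second.expected_modified_steps == b.expected_modified_steps

    def test_colonization_scales_as_n_to_three_halves(self):
        ns = [100, 400, 1600, 6400]
        ts = [float(lollipop_exact(n).first.expected_modified_steps) for n in ns]
        slope = fit_loglog_slope(ns, ts, top_half=False)
        assert 1.35 <= slope <= 1.65

    def test_real_time_identity_at_every_size(self):
        for n in (9, 25, 100, 400):
            res = lollipop_exact(n).first
            assert res.expected_real_time * n == res.expected_modified_steps


class TestWorstStart:
    def test_backward_5_argmax_is_path_start(self):
        wsr = worst_start_time(backward_graph(5), arithmetic="rational")
        assert wsr.argmax == 0
        assert wsr.value == 50
        assert all(t < 50 for v, t in wsr.per_start.items() if v != 0)

    def test_star_start_independent(self):
        wsr = worst_start_time(star_graph(6), arithmetic="rational")
        assert len(set(wsr.per_start.values())) == 1

    def test_k3_symmetric(self):
        wsr = worst_start_time(complete_graph(3), arithmetic="rational")
        assert len(set(wsr.per_start.values())) == 1

    def test_invalid_starts_excluded(self):
        wsr = worst_start_time(total_order_graph(4), arithmetic="rational")
        assert wsr.excluded_starts == (1, 2, 3)
        assert set(wsr.per_start) == {0}
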