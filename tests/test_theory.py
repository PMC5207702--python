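"""Closed-form activation theory: hypergeometric tolerance, thresholds, Xi."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellfrust.theory import (
    LifetimeModel,
    TheoryParams,
    activation_prob,
    contextual_activation_mc,
    contextual_p,
    discrimination_prob,
    lifetime_estimate,
    prob_missing,
    solve_activation_threshold,
    threshold_by_search,
)


class TestProbMissing:
    def test_normalizes_to_one_over_parameter_grid(self):
        for n_l in (8, 24, 48):
            for n_top in range(2, n_l + 1, 2):
                for n_r in range(0, n_l // 2 + 1):
                    p = TheoryParams(n_ligands=n_l, n_top=n_top, n_rare=n_r)
                    total = sum(prob_missing(f, p) for f in range(n_r + 1))
                    assert total == pytest.approx(1.0, abs=1e-9)

    def test_no_rare_ligands_means_nothing_missing(self):
        p = TheoryParams(n_rare=0)
        assert prob_missing(0, p) == pytest.approx(1.0)

    def test_two_rare_worked_case_by_exhaustive_enumeration(self):
        # 24-ligand block, 12 top: enumerate all 2-subsets of rare positions
        p = TheoryParams(n_ligands=48, n_top=24, n_rare=2)
        top = set(range(12))
        counts = {0: 0, 1: 0, 2: 0}
        for pair in combinations(range(24), 2):
            counts[len(top & set(pair))] += 1
        total = math.comb(24, 2)
        assert prob_missing(0, p) == pytest.approx(counts[0] / total)
        assert prob_missing(1, p) == pytest.approx(counts[1] / total)
        assert activation_prob(p) == pytest.approx(counts[2] / total)
        assert counts[2] / total == pytest.approx(66 / 276)


class TestActivationThreshold:
    def test_printed_worked_example(self):
        assert solve_activation_threshold(TheoryParams()) == 9

    def test_everything_tolerated_needs_at_most_one_cell(self):
        # tail at 0 is identically 1, so the threshold floors at 1
        p = TheoryParams(alpha=0.999)
        assert solve_activation_threshold(p) <= 1

    def test_fixed_point_equals_direct_tail_search_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p_act = float(rng.uniform(0.01, 0.95))
            alpha = float(rng.uniform(0.02, 0.5))
            params = TheoryParams(alpha=alpha)
            assert solve_activation_threshold(params, p_act) == threshold_by_search(
                params, p_act
            )

    @given(st.integers(0, 10), st.floats(0.05, 0.4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_threshold_controls_self_tail(self, n_rare, alpha):
        params = TheoryParams(n_rare=n_rare, alpha=alpha)
        thres = solve_activation_threshold(params)
        assert discrimination_prob(params, 0) <= alpha + 1e-12
        assert 0 <= thres <= params.n_ilists + 1


class TestDiscriminationProb:
    def test_monotone_in_extra_rare_ligands(self):
        params = TheoryParams(n_ligands=48, n_top=10, n_rare=1)
        xs = [discrimination_prob(params, d) for d in range(0, 8)]
        assert all(b >= a - 1e-12 for a, b in zip(xs, xs[1:]))

    def test_saturates_toward_full_discrimination(self):
        params = TheoryParams(n_ligands=48, n_top=10, n_rare=1)
        assert discrimination_prob(params, 10) > 0.99


class TestContextualP:
    def test_closed_form_values(self):
        assert contextual_p(0, 48) == (0.0, 0.0)
        p1, p2 = contextual_p(24, 48)
        assert p1 == pytest.approx(1.0)
        assert p2 == pytest.approx(1.0)

    def test_single_draw_probability_by_enumeration(self):
        # N_L=48: central half-block pool has 12 slots; an IList keeps
        # n_c/2 of them on top; count favourable single placements
        n_l = 48
        for n_c in (2, 6, 12):
            kept = set(range(n_c // 2))
            hits = sum(1 for slot in range(n_l // 4) if slot in kept)
            assert contextual_p(n_c, n_l)[0] == pytest.approx(hits / (n_l // 4))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            contextual_p(30, 48)


class TestContextualMC:
    def test_all_central_structure_activates_certainly(self):
        # every IList keeps the full central region on top: p1 = 1 for all,
        # so any threshold up to the population size is always reached
        p = TheoryParams()
        n_c = np.full(24, 24)
        xi, _ = contextual_activation_mc(
            p, 2000, np.random.default_rng(0), n_c_values=n_c
        )
        assert xi == 1.0

    def test_modes_agree_with_exhaustive_enumeration_on_fixed_structure(self):
        # fixed per-IList central counts -> convolution mode is a
        # Poisson-binomial tail, checkable by dynamic programming
        params = TheoryParams()
        n_c = np.array([2 * (d % 13) for d in range(24)])
        xi, se = contextual_activation_mc(
            params, 200_000, np.random.default_rng(3), n_c_values=n_c
        )
        probs = (2.0 * n_c / 48.0) ** 2
        dp = np.zeros(25)
        dp[0] = 1.0
        for p in probs:
            dp[1:] = dp[1:] * (1 - p) + dp[:-1] * p
            dp[0] *= 1 - p
        exact = dp[9:].sum()
        assert xi == pytest.approx(exact, abs=4 * max(se, 1e-4))

    def test_worked_value_reproduced(self):
        xi, se = contextual_activation_mc(
            TheoryParams(), 100_000, np.random.default_rng(11)
        )
        assert xi == pytest.approx(0.135, abs=0.01)


class TestLifetimeModel:
    def test_no_destabilizers_is_infinite(self):
        m = LifetimeModel({}, {("k", None): 0.3})
        assert lifetime_estimate(m, ("i", "j")) == math.inf

    def test_homogeneity_doubling_frequencies_halves_lifetime(self):
        pair = ("i", "j")
        m1 = LifetimeModel({(("k", "p"), pair): 2}, {("k", "p"): 0.25})
        m2 = LifetimeModel({(("k", "p"), pair): 2}, {("k", "p"): 0.5})
        assert lifetime_estimate(m1, pair) == pytest.approx(
            2 * lifetime_estimate(m2, pair)
        )

    def test_ranking_anti_monotone_in_destabilization_pressure(self):
        freq = {("k", None): 0.2, ("q", None): 0.2}
        weak = LifetimeModel({(("k", None), "a"): 1}, freq)
        strong = LifetimeModel(
            {(("k", None), "b"): 1, (("q", None), "b"): 3}, freq
        )
        assert lifetime_estimate(weak, "a") > lifetime_estimate(strong, "b")
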