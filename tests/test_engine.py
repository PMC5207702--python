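"""Frustrated matching dynamics: decision rule, determinism, invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cellfrust.engine import (
    Population,
    Simulation,
    _PyState,
    build_pref,
    decide,
    interaction_step,
    perceived_rank,
    random_ranks,
    run_window_python,
)


def _fresh_state(n):
    return _PyState(
        np.full(n, -1, np.int32), np.full(n, -1, np.int32), np.zeros(n, np.int64)
    )


class TestPerceivedRank:
    def test_top_and_bottom_positions(self, small_pop):
        j = 0
        ilist = small_pop.ilists[j]
        top, bottom = int(ilist[0]), int(ilist[-1])
        assert perceived_rank(small_pop.ranks, j, top // 2, top) == 0
        assert perceived_rank(small_pop.ranks, j, bottom // 2, bottom) == 2 * small_pop.n - 1

    def test_moving_a_symbol_to_the_bottom_updates_its_rank(self, small_pop):
        # recompute by explicit list scan after the move
        j, n = 1, small_pop.n
        order = list(small_pop.ilists[j])
        sym = order[0]
        order = order[1:] + [sym]
        ranks = small_pop.ranks.copy()
        ranks[j, order] = np.arange(2 * n)
        assert int(ranks[j, sym]) == 2 * n - 1
        assert [int(ranks[j, s]) for s in order] == sorted(
            int(ranks[j, s]) for s in order
        )

    def test_foreign_symbol_rejected(self, small_pop):
        with pytest.raises(ValueError):
            perceived_rank(small_pop.ranks, 0, 1, 7)  # symbol 7 belongs to APC 3
        with pytest.raises(IndexError):
            perceived_rank(small_pop.ranks, 0, 9, 18)


class TestDecide:
    def test_both_free_always_match(self, small_pop):
        pref = build_pref(small_pop.ranks, np.zeros(small_pop.n, bool))
        state = _fresh_state(small_pop.n)
        assert decide(
            pref, small_pop.apc_subtype, small_pop.t_subtype, state, 0, 0
        ) == (True, True)

    def test_higher_ranked_apc_frustrates_existing_conjugate(self):
        # the third-party APC whose displayed ligand outranks the current
        # partner's draws the T cell away; a lower-ranked one does not
        n = 4
        rng = np.random.default_rng(0)
        pop = Population.random(n, rng)
        pref = build_pref(pop.ranks, np.zeros(n, bool))
        j = 0
        order = np.argsort(pref[j])  # APCs from most to least preferred
        best, mid = int(order[0]), int(order[1])
        state = _fresh_state(n)
        state.t_partner[j] = mid
        state.a_partner[mid] = j
        asub, tsub = pop.apc_subtype, pop.t_subtype
        t_pref, _ = decide(pref, asub, tsub, state, j, best)
        assert t_pref
        worst = int(order[-1])
        t_pref, _ = decide(pref, asub, tsub, state, j, worst)
        assert not t_pref

    def test_apc_keeps_same_subtype_partner_against_any_tcell(self):
        n = 4
        pop = Population.random(n, np.random.default_rng(1))
        pref = build_pref(pop.ranks, np.zeros(n, bool))
        state = _fresh_state(n)
        # APC 0 (subtype I) conjugated with T cell 0 (subtype I)
        state.a_partner[0] = 0
        state.t_partner[0] = 0
        # T cell 1 (subtype I, tie) and T cell 2 (subtype II, worse): the
        # APC side never strictly prefers them over a same-subtype partner
        _, a_pref = decide(pref, pop.apc_subtype, pop.t_subtype, state, 1, 0)
        assert not a_pref
        _, a_pref = decide(pref, pop.apc_subtype, pop.t_subtype, state, 2, 0)
        assert not a_pref

    def test_remeeting_current_partner_keeps_without_reset(self, small_pop):
        pref = build_pref(small_pop.ranks, np.zeros(small_pop.n, bool))
        state = _fresh_state(small_pop.n)
        state.t_partner[2] = 3
        state.a_partner[3] = 2
        assert decide(
            pref, small_pop.apc_subtype, small_pop.t_subtype, state, 2, 3
        ) == (False, False)


class TestInteractionStep:
    def test_lone_pair_never_destabilized(self):
        # 2-cell system: once the same-subtype pair forms nothing breaks it
        pop = Population.random(2, np.random.default_rng(3))
        pref = build_pref(pop.ranks, np.zeros(2, bool))
        state = _fresh_state(2)
        rev = pop.reverse_connectivity()
        rng = np.random.default_rng(5)
        for _ in range(200):
            interaction_step(
                pop, state, pref, int(rng.integers(4)), float(rng.random()), rev
            )
        assert state.t_partner[0] >= 0 or state.t_partner[1] >= 0
        displaced = [e for e in state.events if e[4] == "displaced"]
        # same-subtype conjugates are only displaced by strictly better offers,
        # which a single same-subtype APC pair cannot produce
        for e in displaced:
            assert e[3] >= 0

    def test_matching_invariant_each_cell_in_at_most_one_conjugate(self, small_pop):
        pref = build_pref(small_pop.ranks, np.zeros(small_pop.n, bool))
        state = _fresh_state(small_pop.n)
        rev = small_pop.reverse_connectivity()
        rng = np.random.default_rng(7)
        for _ in range(500):
            interaction_step(
                small_pop, state, pref,
                int(rng.integers(2 * small_pop.n)), float(rng.random()), rev,
            )
            tp, ap = state.t_partner, state.a_partner
            for j in range(small_pop.n):
                if tp[j] >= 0:
                    assert ap[tp[j]] == j
            for i in range(small_pop.n):
                if ap[i] >= 0:
                    assert tp[ap[i]] == i

    def test_stationary_occupancy_matches_exact_markov_chain(self):
        """2x2 system vs brute-force enumeration of the decision dynamics.

        The chain over matchings is built here independently from first
        principles (mutual strict preference; APC prefers its own subtype)
        and its stationary law is compared with empirical state frequencies.
        """
        n = 2
        rng = np.random.default_rng(11)
        pop = Population.random(n, rng)
        rare = np.zeros(n, bool)
        pref = build_pref(pop.ranks, rare)

        states = [frozenset(), frozenset({(0, 0)}), frozenset({(0, 1)}),
                  frozenset({(1, 0)}), frozenset({(1, 1)}),
                  frozenset({(0, 0), (1, 1)}), frozenset({(0, 1), (1, 0)})]
        index = {s: k for k, s in enumerate(states)}

        def apc_sub(i):
            return i >= n // 2

        def transition(state, i, j):
            # independent re-statement of the rule: each side that strictly
            # prefers the candidate detaches; the pair forms iff both do
            cur_a = next((a for a, t in state if t == j), None)
            cur_t = next((t for a, t in state if a == i), None)
            if cur_a == i:
                return state
            t_pref = cur_a is None or pref[j, i] < pref[j, cur_a]
            a_pref = cur_t is None or (
                apc_sub(i) == (j >= n // 2) and (cur_t >= n // 2) != apc_sub(i)
            )
            pairs = set(state)
            if t_pref and cur_a is not None:
                pairs.discard((cur_a, j))
            if a_pref and cur_t is not None:
                pairs.discard((i, cur_t))
            if t_pref and a_pref:
                pairs.add((i, j))
            return frozenset(pairs)

        P = np.zeros((7, 7))
        draws = [(i, j) for i in range(n) for j in range(n)]
        for s in states:
            for i, j in draws:
                # either side may be drawn first; the tested pair is the same
                P[index[s], index[transition(s, i, j)]] += 1 / len(draws)
        evals, evecs = np.linalg.eig(P.T)
        stat = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
        stat = stat / stat.sum()

        sim_state = _fresh_state(n)
        rev = pop.reverse_connectivity()
        counts = np.zeros(7)
        steps = 40_000
        for _ in range(steps):
            interaction_step(
                pop, sim_state, pref, int(rng.integers(2 * n)), float(rng.random()), rev
            )
            pairs = frozenset(
                (int(sim_state.t_partner[j]), j)
                for j in range(n)
                if sim_state.t_partner[j] >= 0
            )
            counts[index[pairs]] += 1
        emp = counts / steps
        assert np.abs(emp - stat).max() < 0.02


class TestRunWindow:
    def test_zero_window_zero_counts(self, small_pop, rng):
        sim = Simulation([small_pop], rng)
        counts = sim.run_window(np.zeros(small_pop.n, bool), 0, tau_act=5)
        assert counts.c0.sum() == 0 and counts.c_act.sum() == 0

    def test_kernel_reproduces_python_reference_exactly(self, small_pop):
        rare = np.zeros(small_pop.n, bool)
        rare[3] = True
        ref_counts, ref_state = run_window_python(
            small_pop.copy(), rare, 800, np.random.default_rng(99)
        )
        sim = Simulation([small_pop.copy()], np.random.default_rng(99))
        kern = sim.run_window(rare, 800, tau_act=5, record_events=True)
        cols = ["time", "apc_index", "tcell_index", "duration"]
        ref = ref_counts.events[cols].reset_index(drop=True).astype(np.int64)
        got = kern.events[cols].reset_index(drop=True).astype(np.int64)
        pd.testing.assert_frame_equal(ref, got)
        assert np.array_equal(ref_counts.c0, kern.c0)
        assert np.array_equal(ref_counts.c_act, kern.c_act)

    def test_identical_seed_identical_event_log(self, small_pop):
        logs = []
        for _ in range(2):
            sim = Simulation([small_pop.copy()], np.random.default_rng(123))
            counts = sim.run_window(
                np.zeros(small_pop.n, bool), 1000, tau_act=5,
                anergy_tau=40, record_events=True,
            )
            logs.append(counts.events)
        pd.testing.assert_frame_equal(logs[0], logs[1])

    def test_counts_monotone_in_duration_threshold(self, small_pop, rng):
        sim = Simulation([small_pop], rng)
        counts = sim.run_window(
            np.zeros(small_pop.n, bool), 3000, tau_act=5, record_events=True
        )
        prev = counts.counts_at(0)
        assert np.array_equal(prev, counts.c0)
        for tau in (1, 5, 20, 100, 500):
            cur = counts.counts_at(tau)
            assert np.all(cur <= prev)
            prev = cur

    def test_anergy_caps_every_duration(self, small_pop, rng):
        sim = Simulation([small_pop], rng)
        counts = sim.run_window(
            np.zeros(small_pop.n, bool), 4000, tau_act=10,
            anergy_tau=25, record_events=True,
        )
        assert counts.events["duration"].max() <= 25
        anergized = counts.events[counts.events["cause"] == "anergy"]
        assert (anergized["duration"] == 25).all()

    def test_total_counts_equal_event_tally(self, small_pop, rng):
        sim = Simulation([small_pop], rng)
        counts = sim.run_window(
            np.zeros(small_pop.n, bool), 2500, tau_act=5,
            anergy_tau=30, record_events=True,
        )
        assert counts.c0.sum() == len(counts.events)
        assert counts.c_act.sum() == (counts.events["duration"] >= 5).sum()

    def test_batch_windows_deterministic_and_consistent(self, small_pop):
        rare = np.zeros((5, small_pop.n), dtype=bool)
        rare[2, 1] = True
        outs = []
        for _ in range(2):
            sim = Simulation([small_pop.copy()], np.random.default_rng(7))
            outs.append(sim.run_windows(rare, 2000, tau_act=40, anergy_tau=40))
        for a, b in zip(outs[0], outs[1]):
            assert np.array_equal(a, b)
        cact, c0, tcact = outs[0]
        assert np.all(cact <= c0)
        assert cact.sum() == tcact.sum()


class TestPopulation:
    def test_rejects_bad_shapes_and_connectivity(self, rng):
        with pytest.raises(ValueError):
            Population(n=3, ranks=np.zeros((3, 6), dtype=np.int32))
        with pytest.raises(ValueError):
            Population(n=4, ranks=np.zeros((4, 4), dtype=np.int32))
        ranks = random_ranks(4, rng)
        conn = np.array([[0, 0]] * 4, dtype=np.int32)
        with pytest.raises(ValueError):
            Population(n=4, ranks=ranks, conn=conn)

    def test_snapshot_roundtrip(self, small_pop):
        restored = Population.from_json(small_pop.to_json())
        assert restored.n == small_pop.n
        assert np.array_equal(restored.ranks, small_pop.ranks)
        assert np.array_equal(restored.conn, small_pop.conn)

    def test_ilists_are_permutations(self, small_pop):
        il = small_pop.ilists
        for j in range(small_pop.n):
            assert sorted(il[j]) == list(range(2 * small_pop.n))
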