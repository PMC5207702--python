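"""Thymic negative selection of T-cell repertoires.

Education eliminates every T cell whose conjugation age reaches the current
lifetime threshold ``tau_n`` and replaces it by a naive cell (same
connectivity, fresh random IList).  ``tau_n`` starts unbounded; whenever a
full window of ``W_tau`` iterations passes without an elimination, it is
lowered to the largest conjugation duration observed in that window
(terminated durations and still-open ages) and the population is recorded.
The displayed self configuration changes every ``T_s`` iterations.
Education stops once ``tau_n`` has been stable for ``stop_window``
iterations; the last recorded population is the educated one.

Short presentation intervals matter: to be eliminated a cell must lack its
surveyed frequent ligands in consecutive configurations, which for a ligand
rare with frequency ``p_R`` happens with probability ``p_R**2`` — small
``T_s`` therefore tolerates a few rare same-subtype ligands in top
positions and improves generalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import INF_TAU, educate_kernel
from .engine import Population, random_ranks

__all__ = [
    "EducationParams",
    "EducationTrace",
    "negative_selection",
    "build_repertoire",
    "ilist_balance_stats",
    "consecutive_presentation_prob",
]


@dataclass
class EducationParams:
    """Negative-selection schedule (all windows in sweep iterations).

    One iteration is a sweep of 2N elementary pairwise contacts.

    w_tau : update-window length after which tau_n is lowered (iterations)
    t_s : iterations between configuration changes
    stop_window : iterations of unchanged tau_n required to stop
    n_populations : educated populations per repertoire
    max_iter : hard safety cap on total iterations
    elim_tol : max eliminations per window that still allow a tau_n update
        (default N/16).  The strict zero-elimination reading deadlocks: the
        two-level APC preference makes same-subtype matchings absorbing, so
        a standing elimination/replacement mill never fully quiets.
    """

    w_tau: int = 10_000
    t_s: int = 100
    stop_window: int = 1_000_000
    n_populations: int = 10
    max_iter: int = 20_000_000
    elim_tol: int | None = None

    def __post_init__(self) -> None:
        if min(self.w_tau, self.t_s, self.stop_window, self.n_populations) <= 0:
            raise ValueError("all education parameters must be positive")
        if self.t_s > self.w_tau:
            raise ValueError("t_s must not exceed w_tau")


@dataclass
class EducationTrace:
    """tau_n update history and per-slot elimination counts."""

    updates: pd.DataFrame
    elim_counts: np.ndarray
    total_iterations: int
    converged: bool

    @property
    def final_tau(self) -> float:
        """Final lifetime threshold in sweep iterations."""
        return float(self.updates["tau_n"].iloc[-1]) if len(self.updates) else float("nan")

    def write(self, path) -> None:
        self.updates.to_csv(path, index=False)


def consecutive_presentation_prob(p_rare: float) -> float:
    """Probability a ligand with presentation frequency p appears in two
    consecutive configurations (the escape route that lets rare same-subtype
    ligands survive on top positions when T_s is small)."""
    return p_rare * p_rare


def _normalize_stream(configs, n: int) -> np.ndarray:
    arr = np.asarray(configs)
    if arr.ndim == 2:  # (S, n) shared perception
        arr = arr[:, None, :]
    if arr.ndim != 3 or arr.shape[2] != n:
        raise ValueError("configuration stream must be (S, n) or (S, n_t, n)")
    return np.ascontiguousarray(arr.astype(np.uint8))


def negative_selection(
    pop: Population,
    self_stream,
    params: EducationParams,
    rng: np.random.Generator,
    chunk: int = 200_000,
) -> tuple[Population, EducationTrace]:
    """Educate ``pop`` in place against a cycling stream of self configurations.

    ``self_stream``: array of rare-flag configurations, shape ``(S, n)``
    (shared perception, e.g. DinBs) or ``(S, n_t, n)`` (per-cell
    perception).  The stream cycles; one configuration is displayed per
    ``t_s``-iteration slot.  Returns the last recorded (educated) population
    and the education trace.
    """
    n = pop.n
    sweep = 2 * n
    elim_tol = params.elim_tol if params.elim_tol is not None else max(1, n // 16)
    rare_s = _normalize_stream(self_stream, n)
    rev = pop.reverse_connectivity()
    asub, tsub = pop.apc_subtype, pop.t_subtype
    ranks = pop.ranks  # mutated in place
    pref = np.zeros((n, n), dtype=np.int32)
    t_partner = np.full(n, -1, np.int32)
    a_partner = np.full(n, -1, np.int32)
    a_start = np.zeros(n, np.int64)
    state = np.zeros(10, dtype=np.int64)
    state[1] = INF_TAU
    cap = 4096
    trace_iter = np.zeros(cap, np.int64)
    trace_tau = np.zeros(cap, np.int64)
    elim_counts = np.zeros(n, np.int64)
    snap = np.zeros_like(ranks)

    perm_pool = 512
    max_draws = params.max_iter * sweep
    while state[7] == 0 and state[0] < max_draws:
        cell_draws = rng.integers(0, 2 * n, size=chunk, dtype=np.int64)
        u_partner = rng.random(chunk)
        perms = np.stack(
            [rng.permutation(2 * n).astype(np.int64) for _ in range(perm_pool)]
        )
        consumed = 0
        while consumed < chunk and state[7] == 0:
            used = educate_kernel(
                ranks, pref, rare_s, asub, tsub, pop.conn, rev,
                cell_draws[consumed:], u_partner[consumed:], perms,
                t_partner, a_partner, a_start,
                state, params.t_s * sweep, params.w_tau * sweep,
                params.stop_window * sweep, sweep, elim_tol,
                trace_iter, trace_tau, elim_counts, snap,
            )
            consumed += used
            if used == 0 or state[5] >= perm_pool - 1:
                # permutation pool exhausted mid-chunk: refresh
                perms = np.stack(
                    [rng.permutation(2 * n).astype(np.int64) for _ in range(perm_pool)]
                )
                state[5] = 0
            if state[0] >= max_draws:
                break
    if state[8] == 0:
        raise RuntimeError(
            "education ended before any tau_n update; increase max_iter or "
            "shorten w_tau"
        )
    updates = pd.DataFrame(
        {
            "iteration": trace_iter[: state[6]] / sweep,
            "tau_n": trace_tau[: state[6]] / sweep,
        }
    )
    educated = Population(n=n, ranks=snap.copy(), conn=pop.conn.copy(), seed=pop.seed)
    trace = EducationTrace(
        updates=updates,
        elim_counts=elim_counts,
        total_iterations=int(state[0]) // sweep,
        converged=bool(state[7]),
    )
    return educated, trace


def build_repertoire(
    n: int,
    self_stream,
    params: EducationParams,
    rng: np.random.Generator,
    conn: np.ndarray | None = None,
) -> tuple[list[Population], list[EducationTrace]]:
    """Educate ``n_populations`` independent populations sharing connectivity."""
    pops, traces = [], []
    for _ in range(params.n_populations):
        naive = Population(n=n, ranks=random_ranks(n, rng), conn=None if conn is None else conn.copy())
        educated, trace = negative_selection(naive, self_stream, params, rng)
        pops.append(educated)
        traces.append(trace)
    return pops, traces


# ---------------------------------------------------------------------------
# IList diagnostics
# ---------------------------------------------------------------------------


def first_lscs_rank(pop: Population) -> np.ndarray:
    """Per T cell, IList position of its highest-ranked same-subtype symbol."""
    n = pop.n
    half = n // 2
    out = np.empty(n, dtype=np.int64)
    for j in range(n):
        lscs_apcs = np.arange(0, half) if j < half else np.arange(half, n)
        syms = np.concatenate([2 * lscs_apcs, 2 * lscs_apcs + 1])
        out[j] = pop.ranks[j, syms].min()
    return out


def ilist_balance_stats(pop: Population) -> pd.DataFrame:
    """Frequent LOCS of each opposite-subtype block above the first LSCS.

    Requires the DinBs labelling (two equal blocks per APC subtype).  After
    education both blocks should be represented above the first same-subtype
    symbol in nearly all ILists, which guarantees a minimum number of
    surveyed frequent ligands in every self configuration.
    """
    n = pop.n
    if n % 4:
        raise ValueError("DinBs labelling requires n divisible by 4")
    half, nb = n // 2, n // 4
    cut = first_lscs_rank(pop)
    rows = []
    for j in range(n):
        locs0 = np.arange(half, half + nb) if j < half else np.arange(0, nb)
        locs1 = locs0 + nb
        above_a = int((pop.ranks[j, 2 * locs0] < cut[j]).sum())
        above_b = int((pop.ranks[j, 2 * locs1] < cut[j]).sum())
        rows.append(
            {
                "tcell": j,
                "subtype": int(j >= half),
                "first_lscs_rank": int(cut[j]),
                "block_a_top": above_a,
                "block_b_top": above_b,
            }
        )
    return pd.DataFrame(rows)
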