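"""Discrete-time frustrated conjugation dynamics between APCs and T cells.

The model is a deliberately unstable variant of the Gale–Shapley matching
dynamics.  ``2N`` agents — ``N`` antigen-presenting cells (APCs) and ``N``
T cells, each split into two equal subtypes — interact at discrete time
steps: a random cell meets a random cell of the opposite type from its
connectivity list.  Each side that strictly prefers the candidate over its
current partner re-directs its synapse — it detaches from its current
conjugate whether or not the candidate reciprocates — and a new conjugate
forms when both sides are willing (free cells accept anything).  Terminated
conjugations have their durations recorded.  Because T cells rank
opposite-subtype ligands on
top, conjugations are perpetually destabilized ("frustrated") and self
configurations only produce short lifetimes; long-lived conjugations are the
detection signal.

T cells rank *perceived* symbols: each APC ``i`` is perceived as either a
frequent (``F_i``) or rare (``R_i``) signal, so an interaction list (IList)
is a total order over ``2K`` symbols.  Symbols are encoded ``2*i + r`` with
``r=1`` for rare.  APCs have an implicit two-entry list: T cells of their
own subtype strictly first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import run_batch_kernel, run_window_kernel

__all__ = [
    "Population",
    "Simulation",
    "LifetimeCounts",
    "random_ranks",
    "perceived_rank",
    "decide",
    "interaction_step",
]

_EVENT_CAUSES = {0: "displaced", 1: "anergy", 2: "window_end"}


def random_ranks(n: int, rng: np.random.Generator, n_tcells: int | None = None) -> np.ndarray:
    """Random ILists for ``n_tcells`` T cells over ``2n`` perceived symbols.

    Returns the rank matrix: ``ranks[j, sym]`` is the 0-based position of
    symbol ``sym`` in T cell ``j``'s IList (lower = preferred).
    """
    n_tcells = n if n_tcells is None else n_tcells
    ranks = np.empty((n_tcells, 2 * n), dtype=np.int32)
    for j in range(n_tcells):
        perm = rng.permutation(2 * n)
        ranks[j, perm] = np.arange(2 * n, dtype=np.int32)
    return ranks


@dataclass
class Population:
    """All cells of one system: subtypes, connectivity and ILists.

    ``n`` APCs and ``n`` T cells; indices below ``n//2`` are subtype I.
    ``conn[j]`` lists the APCs T cell ``j`` can interact with (default: all).
    """

    n: int
    ranks: np.ndarray
    conn: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n % 2:
            raise ValueError("n must be even (two equal subtypes)")
        self.ranks = np.ascontiguousarray(self.ranks, dtype=np.int32)
        if self.ranks.shape != (self.n, 2 * self.n):
            raise ValueError("ranks must have shape (n, 2n)")
        if self.conn is None:
            self.conn = np.tile(np.arange(self.n, dtype=np.int32), (self.n, 1))
        self.conn = np.ascontiguousarray(self.conn, dtype=np.int32)
        if len(np.unique(self.conn[0])) != self.conn.shape[1]:
            raise ValueError("connectivity entries must be distinct")
        if self.conn.shape[1] == 0:
            raise ValueError("connectivity must be non-empty")

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "Population":
        return cls(n=n, ranks=random_ranks(n, rng))

    @property
    def apc_subtype(self) -> np.ndarray:
        return (np.arange(self.n) >= self.n // 2).astype(np.uint8)

    @property
    def t_subtype(self) -> np.ndarray:
        return (np.arange(self.n) >= self.n // 2).astype(np.uint8)

    @property
    def ilists(self) -> np.ndarray:
        """ilists[j, pos] = symbol at IList position pos (inverse of ranks)."""
        out = np.empty_like(self.ranks)
        pos = self.ranks
        for j in range(self.n):
            out[j, pos[j]] = np.arange(2 * self.n, dtype=np.int32)
        return out

    def reverse_connectivity(self) -> np.ndarray:
        """rev[i] = T cells listing APC i (requires a regular design)."""
        lists = [[] for _ in range(self.n)]
        for j in range(self.n):
            for i in self.conn[j]:
                lists[int(i)].append(j)
        deg = {len(l) for l in lists}
        if len(deg) != 1 or 0 in deg:
            raise ValueError("connectivity must give every APC the same positive degree")
        return np.asarray(lists, dtype=np.int32)

    def copy(self) -> "Population":
        return Population(self.n, self.ranks.copy(), self.conn.copy(), self.seed)

    def to_json(self) -> dict:
        return {
            "n": self.n,
            "ranks": self.ranks.tolist(),
            "conn": self.conn.tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Population":
        return cls(
            n=int(obj["n"]),
            ranks=np.asarray(obj["ranks"], dtype=np.int32),
            conn=np.asarray(obj["conn"], dtype=np.int32),
            seed=obj.get("seed"),
        )


@dataclass
class LifetimeCounts:
    """Per-APC conjugation-duration counts over one window.

    ``c0[i]`` counts all conjugations involving APC ``i`` terminated (or
    anergy-capped) inside the window; ``c_act[i]`` those with duration at
    least ``tau_act``.  With an event log attached, counts at any other
    duration are available through :meth:`counts_at`.
    """

    c0: np.ndarray
    c_act: np.ndarray
    tau_act: int
    window: int
    events: pd.DataFrame | None = None

    def counts_at(self, tau: int) -> np.ndarray:
        if self.events is None:
            raise ValueError("window was run without event logging")
        n = len(self.c0)
        sel = self.events[self.events["duration"] >= tau]
        return np.bincount(sel["apc_index"].to_numpy(), minlength=n)

    def write_event_log(self, path) -> None:
        if self.events is None:
            raise ValueError("window was run without event logging")
        self.events.to_csv(path, index=False)


def build_pref(ranks: np.ndarray, rare: np.ndarray) -> np.ndarray:
    """Perceived-preference matrix pref[j, i] = rank of F_i/R_i in IList j.

    ``rare`` is boolean, shape ``(n,)`` (shared perception) or ``(n_t, n)``.
    """
    n_t = ranks.shape[0]
    n = ranks.shape[1] // 2
    rare = np.asarray(rare)
    if rare.ndim == 1:
        rare = np.broadcast_to(rare, (n_t, n))
    sym = (2 * np.arange(n)[None, :] + rare.astype(np.int64))
    return np.take_along_axis(ranks, sym.astype(np.int64), axis=1).astype(np.int32)


class Simulation:
    """Mutable world: population(s), current conjugations and the clock.

    ``populations`` is the anergy-replacement repertoire; member 0 is the
    active detecting population.  All members must share connectivity (the
    replacement cell keeps the eliminated cell's connectivity slot).
    """

    def __init__(
        self,
        populations: Population | list[Population],
        rng: np.random.Generator,
    ) -> None:
        if isinstance(populations, Population):
            populations = [populations]
        base = populations[0]
        for p in populations[1:]:
            if not np.array_equal(p.conn, base.conn):
                raise ValueError("repertoire members must share connectivity")
        self.populations = populations
        self.n = base.n
        self.rng = rng
        self.conn = base.conn
        self.rev = base.reverse_connectivity()
        self.asub = base.apc_subtype
        self.tsub = base.t_subtype
        self.ranks_all = np.stack([p.ranks for p in populations])
        self.cur_member = np.zeros(self.n, dtype=np.int32)
        self.t_partner = np.full(self.n, -1, dtype=np.int32)
        self.a_partner = np.full(self.n, -1, dtype=np.int32)
        self.a_start = np.zeros(self.n, dtype=np.int64)
        self.time = 0

    # -- perception -------------------------------------------------------
    def _pref_repertoire(self, rare) -> np.ndarray:
        """(R, n_t, n) preference matrices, one per repertoire member.

        ``rare``: (n,) or (n_t, n) shared across members, or (R, n_t, n).
        """
        rare = np.asarray(rare)
        R = len(self.populations)
        if rare.ndim < 3:
            return np.stack([build_pref(self.ranks_all[r], rare) for r in range(R)])
        if rare.shape[0] != R:
            raise ValueError("per-member rare matrix must have one slab per member")
        return np.stack([build_pref(self.ranks_all[r], rare[r]) for r in range(R)])

    # -- dynamics ---------------------------------------------------------
    def run_window(
        self,
        rare,
        window: int,
        tau_act: int = 5,
        anergy_tau: int | None = None,
        record_events: bool = False,
    ) -> LifetimeCounts:
        """Run ``window`` interaction steps under perception ``rare``.

        Conjugations persist across successive windows (durations are
        measured on the global clock); counts are per window.  With
        ``anergy_tau`` set, conjugations reaching that age are terminated,
        counted, and the T cell is replaced by the repertoire member drawn
        uniformly for its slot.
        """
        if window < 0:
            raise ValueError("window must be non-negative")
        n = self.n
        pref_rep = self._pref_repertoire(rare)
        pref = np.ascontiguousarray(pref_rep[self.cur_member, np.arange(n), :])
        cell_draws = self.rng.integers(0, 2 * n, size=window, dtype=np.int64)
        u_partner = self.rng.random(window)
        at = int(anergy_tau) if anergy_tau else 0
        u_rep = self.rng.random(window) if at else np.zeros(1)
        ring = np.full(max(at, 1), -1, dtype=np.int32)
        c0 = np.zeros(n, dtype=np.int64)
        cact = np.zeros(n, dtype=np.int64)
        cap = 3 * window + 1
        ev = [np.zeros(cap, dtype=np.int64) for _ in range(4)]
        ev_cause = np.zeros(cap, dtype=np.int8)
        n_ev = run_window_kernel(
            pref, self.asub, self.tsub, self.conn, self.rev,
            cell_draws, u_partner, u_rep,
            self.t_partner, self.a_partner, self.a_start, self.cur_member,
            self.time, at, pref_rep, ring,
            c0, cact, int(tau_act),
            ev[0], ev[1], ev[2], ev[3], ev_cause, record_events,
        )
        self.time += window
        events = None
        if record_events:
            events = pd.DataFrame(
                {
                    "time": ev[0][:n_ev],
                    "apc_index": ev[1][:n_ev],
                    "tcell_index": ev[2][:n_ev],
                    "duration": ev[3][:n_ev],
                    "cause": pd.Categorical.from_codes(
                        ev_cause[:n_ev], categories=list(_EVENT_CAUSES.values())
                    ),
                }
            )
        return LifetimeCounts(c0, cact, int(tau_act), window, events)

    def run_windows(
        self,
        rare_stack,
        window: int,
        tau_act: int,
        anergy_tau: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Batched consecutive windows, one per sample in ``rare_stack``.

        ``rare_stack``: (S, n) shared perception, (S, n_t, n) per-cell, or
        (S, R, n_t, n) per repertoire member.  Requires full connectivity
        (the fast path used by the calibration/detection protocols).  Returns per-window count arrays
        ``(c_act, c0, t_c_act)``: long and total conjugation counts per APC,
        and long counts attributed to T-cell slots.
        """
        if self.conn.shape[1] != self.n or not np.array_equal(
            self.conn[0], np.arange(self.n)
        ):
            raise ValueError("batched windows require full connectivity")
        rare_stack = np.asarray(rare_stack)
        if rare_stack.ndim == 2:       # (S, n): shared perception
            rare_stack = rare_stack[:, None, None, :]
        elif rare_stack.ndim == 3:     # (S, n_t, n): per-cell, shared members
            rare_stack = rare_stack[:, None, :, :]
        if rare_stack.ndim != 4:
            raise ValueError("rare_stack must be (S, n), (S, n_t, n) or (S, R, n_t, n)")
        rare_stack = np.ascontiguousarray(rare_stack.astype(np.uint8))
        s = rare_stack.shape[0]
        n = self.n
        c0 = np.zeros((s, n), dtype=np.int64)
        cact = np.zeros((s, n), dtype=np.int64)
        tcact = np.zeros((s, n), dtype=np.int64)
        seed = int(self.rng.integers(2**31))
        at = int(anergy_tau) if anergy_tau else 0
        self.time = run_batch_kernel(
            self.ranks_all, rare_stack, self.asub, self.tsub,
            seed, int(window), at, int(tau_act),
            self.t_partner, self.a_partner, self.a_start, self.cur_member,
            self.time, c0, cact, tcact,
        )
        return cact, c0, tcact

    def reset_conjugations(self) -> None:
        self.t_partner[:] = -1
        self.a_partner[:] = -1


# ---------------------------------------------------------------------------
# Reference (pure-python) single-step dynamics; used by tests and tiny runs
# ---------------------------------------------------------------------------


@dataclass
class _PyState:
    t_partner: np.ndarray
    a_partner: np.ndarray
    a_start: np.ndarray
    time: int = 0
    events: list = field(default_factory=list)


def perceived_rank(ranks: np.ndarray, j: int, apc_index: int, symbol: int) -> int:
    """0-based IList position of ``symbol``; lower = preferred."""
    n = ranks.shape[1] // 2
    if not 0 <= symbol < 2 * n:
        raise IndexError(f"symbol {symbol} outside the 2K-symbol alphabet")
    if symbol // 2 != apc_index:
        raise ValueError("symbol does not belong to the given APC")
    return int(ranks[j, symbol])


def decide(pref, asub, tsub, state: _PyState, j: int, i: int) -> tuple[bool, bool]:
    """Strict-preference decisions of a drawn (T cell, APC) encounter.

    Returns ``(t_prefers, a_prefers)``: each side strictly prefers the
    candidate over its current partner (a free cell accepts anything).  A
    side that prefers the candidate re-directs its synapse — it detaches
    from its current conjugate whether or not the candidate reciprocates —
    and the new conjugate forms only when both prefer.  An APC ranks
    same-subtype T cells strictly first and is otherwise indifferent
    (indifference keeps the current partner).  Re-meeting the current
    partner keeps the conjugate without resetting its clock.
    """
    cur_a = state.t_partner[j]
    if cur_a == i:
        return False, False
    t_pref = cur_a == -1 or pref[j, i] < pref[j, cur_a]
    cur_t = state.a_partner[i]
    a_pref = cur_t == -1 or (tsub[j] == asub[i] and tsub[cur_t] != asub[i])
    return t_pref, a_pref


def interaction_step(
    pop: Population,
    state: _PyState,
    pref: np.ndarray,
    cell_draw: int,
    u_partner: float,
    rev: np.ndarray | None = None,
) -> None:
    """One reference step consuming pre-drawn randomness.

    Mirrors the compiled kernel exactly: draw one of the ``2n`` cells, pick a
    partner uniformly on the opposite side of its connectivity, apply the
    decision rule, record terminated durations in ``state.events``.
    """
    n = pop.n
    asub, tsub = pop.apc_subtype, pop.t_subtype
    rev = pop.reverse_connectivity() if rev is None else rev
    t = state.time
    if cell_draw < n:
        i = cell_draw
        j = int(rev[i, int(u_partner * rev.shape[1])])
    else:
        j = cell_draw - n
        i = int(pop.conn[j, int(u_partner * pop.conn.shape[1])])
    t_pref, a_pref = decide(pref, asub, tsub, state, j, i)
    cur_a = state.t_partner[j]
    cur_t = state.a_partner[i]
    if t_pref and cur_a >= 0:
        state.events.append((t, int(cur_a), j, t - int(state.a_start[cur_a]), "displaced"))
        state.a_partner[cur_a] = -1
        state.t_partner[j] = -1
    if a_pref and cur_t >= 0:
        state.events.append((t, i, int(cur_t), t - int(state.a_start[i]), "displaced"))
        state.t_partner[cur_t] = -1
        state.a_partner[i] = -1
    if t_pref and a_pref:
        state.t_partner[j] = i
        state.a_partner[i] = j
        state.a_start[i] = t
    state.time = t + 1


def run_window_python(
    pop: Population,
    rare,
    window: int,
    rng: np.random.Generator,
    tau_act: int = 5,
) -> tuple[LifetimeCounts, _PyState]:
    """Reference window run (no anergy); returns counts and final state."""
    n = pop.n
    pref = build_pref(pop.ranks, rare)
    rev = pop.reverse_connectivity()
    state = _PyState(
        np.full(n, -1, np.int32), np.full(n, -1, np.int32), np.zeros(n, np.int64)
    )
    cell_draws = rng.integers(0, 2 * n, size=window, dtype=np.int64)
    u_partner = rng.random(window)
    for s in range(window):
        interaction_step(pop, state, pref, int(cell_draws[s]), float(u_partner[s]), rev)
    ev = pd.DataFrame(
        state.events, columns=["time", "apc_index", "tcell_index", "duration", "cause"]
    )
    c0 = np.bincount(ev["apc_index"], minlength=n) if len(ev) else np.zeros(n, int)
    sel = ev[ev["duration"] >= tau_act] if len(ev) else ev
    cact = np.bincount(sel["apc_index"], minlength=n) if len(sel) else np.zeros(n, int)
    return LifetimeCounts(c0, cact, tau_act, window, ev), state
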