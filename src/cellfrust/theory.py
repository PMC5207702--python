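"""Closed-form activation theory for frustrated APC/T-cell populations.

In a maximally frustrated population a T cell becomes activated (establishes
long-lived conjugations with same-subtype APCs) when at least two of the
frequent opposite-subtype ligands (LOCS) it keeps ranked in top positions of
its interaction list are absent from the displayed configuration.  This module
computes, analytically or by Monte Carlo:

* the hypergeometric probability that ``f`` top-ranked frequent LOCS are
  missing when ``N_r`` rare ligands are displayed inside one block,
* the per-cell activation probability ``P_act = 1 - P(0) - P(1)``,
* the whole-system activation threshold ``N_a^thres`` (the smallest number of
  activated T cells whose binomial tail probability under self conditions
  does not exceed the tolerated false-positive rate ``alpha``),
* the whole-system activation probability ``Xi`` when extra rare ligands are
  introduced, and its contextual (split-pattern) counterpart.

A small exact lifetime model for toy instances is also provided: conjugation
lifetimes scale with the reciprocal of the total destabilization pressure,
``tau_ij ~ 1 / sum_kp D_kpij n_kp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, hypergeom


@dataclass
class TheoryParams:
    """Parameters of the block-structured activation theory.

    Attributes
    ----------
    n_ligands : int
        ``N_L``, number of subtype-I APCs (= ligands split over two blocks).
    n_top : int
        ``N_LOCS^top``, number of frequent LOCS ranked in top IList
        positions, balanced over the two blocks (``n_top/2`` each).
    n_rare : int
        ``N_r``, number of rare ligands displayed in a self configuration.
    alpha : float
        Tolerated false-positive rate of whole-system activation.
    damping : float
        ``lambda``, damping factor of the fixed-point threshold iteration.
    """

    n_ligands: int = 48
    n_top: int = 24
    n_rare: int = 2
    alpha: float = 0.1
    damping: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.n_top > self.n_ligands:
            raise ValueError("n_top cannot exceed n_ligands")
        if self.n_top % 2:
            raise ValueError("n_top must be even (balanced over two blocks)")
        if self.damping <= 0:
            raise ValueError("damping must be positive")

    @property
    def n_ilists(self) -> int:
        """Number of distinct ILists (identical pairs -> N_L/2 trials)."""
        return self.n_ligands // 2


def prob_missing(f: int, params: TheoryParams) -> float:
    """Probability that ``f`` top-ranked frequent LOCS are absent.

    The ``N_r`` rare ligands of a self configuration fall uniformly inside
    one block of ``N_L/2`` APCs; each IList keeps ``n_top/2`` frequent LOCS
    of that block on top, so the number of hits is hypergeometric.
    Infeasible ``f`` returns 0.
    """
    block = params.n_ligands // 2
    top_per_block = params.n_top // 2
    return float(hypergeom.pmf(f, block, top_per_block, params.n_rare))


def activation_prob(params: TheoryParams, n_rare: int | None = None) -> float:
    """Per-cell activation probability ``P_act = 1 - P(0) - P(1)``."""
    p = params if n_rare is None else TheoryParams(
        params.n_ligands, params.n_top, n_rare, params.alpha, params.damping
    )
    return max(0.0, 1.0 - prob_missing(0, p) - prob_missing(1, p))


def _tail(n_trials: int, p: float, n: int) -> float:
    """Upper binomial tail P(X >= n)."""
    return float(binom.sf(n - 1, n_trials, p))


def threshold_by_search(params: TheoryParams, p_act: float | None = None) -> int:
    """Smallest integer ``n`` with binomial(N_L/2, P_act) tail P(X >= n) <= alpha."""
    p = activation_prob(params) if p_act is None else p_act
    n_trials = params.n_ilists
    if p <= 0:
        return 0 if params.alpha >= 1 else 0
    for n in range(n_trials + 2):
        if _tail(n_trials, p, n) <= params.alpha:
            return n
    raise RuntimeError("unreachable: tail at n_trials+1 is 0")


def solve_activation_threshold(
    params: TheoryParams,
    p_act: float | None = None,
    max_iter: int = 100_000,
) -> int:
    """Activation threshold ``N_a^thres`` by damped fixed-point iteration.

    Iterates ``N_{a,k+1} = N_{a,k} - floor(lambda * (F(N_a - 1) + alpha - 1))``
    where ``F`` is the binomial CDF over the ``N_L/2`` distinct ILists: the
    iteration is stationary exactly when the upper tail from ``N_a`` is at
    most ``alpha``, so the asymptotic value is the smallest count of
    activated cells that self configurations produce with probability
    ``<= alpha``.  Cross-checked against :func:`threshold_by_search`.
    """
    p = activation_prob(params) if p_act is None else p_act
    n_trials = params.n_ilists
    if not 0.0 <= p <= 1.0:
        raise ValueError("P_act must be a probability")
    na = 0
    for _ in range(max_iter):
        cdf = 1.0 - _tail(n_trials, p, na) if na > 0 else 0.0
        step = math.floor(params.damping * (cdf + params.alpha - 1.0))
        if step == 0:
            return na
        na = min(max(na - step, 0), n_trials + 1)
    raise RuntimeError("fixed-point iteration did not converge")


def discrimination_prob(params: TheoryParams, delta_n_rare: int) -> float:
    """Whole-system activation probability ``Xi(N_r^0 + delta_N_r)``.

    Binomial upper tail from ``N_a^thres`` (solved at the self rare count
    ``params.n_rare``) evaluated at the perturbed per-cell activation
    probability.
    """
    thres = solve_activation_threshold(params)
    p_star = activation_prob(params, params.n_rare + delta_n_rare)
    return _tail(params.n_ilists, p_star, thres)


def contextual_p(n_c: int, n_ligands: int) -> tuple[float, float]:
    """Single- and double-miss probabilities of one IList.

    ``p1 = 2 N_c / N_L`` is the probability that the one rare ligand drawn in
    a central half-block hits one of the IList's ``N_c/2`` top frequent LOCS
    there; missing one on each side has probability ``p1**2 = 4 N_c^2/N_L^2``.
    """
    if not 0 <= n_c <= n_ligands // 2:
        raise ValueError("n_c must lie in [0, n_ligands/2]")
    p1 = 2.0 * n_c / n_ligands
    return p1, p1 * p1


def central_counts(ilists, dinbs) -> np.ndarray:
    """Per-distinct-IList ``N_c``: top frequent LOCS inside the central region.

    ``ilists`` is a population built by
    :func:`cellfrust.dinbs.build_max_frustrated_ilists`;  the central region
    is the half-block on each side of the boundary between the two blocks of
    subtype-I APCs.  Only subtype-II T cells (whose LOCS are the subtype-I
    ligands) are informative; their distinct ILists come in identical pairs.
    """
    from .dinbs import central_slots  # local import to avoid cycle

    left, right = central_slots(dinbs)
    central = set(left) | set(right)
    out = []
    for top in ilists.top_sets_subtype2:
        out.append(len(top & central))
    return np.asarray(out[::2], dtype=int)  # one entry per identical pair


def contextual_activation_mc(
    params: TheoryParams,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
    mode: str = "convolution",
    n_c_values: np.ndarray | None = None,
) -> tuple[float, float]:
    """Monte-Carlo whole-system activation probability for split patterns.

    For the abnormal "contextual" pattern one rare ligand appears in each
    central half-block.  Per draw a population realization is built (random
    balanced top subsets, identical-pair structure) unless fixed
    ``n_c_values`` are supplied, and the number of distinct ILists missing
    two top frequent LOCS is compared with ``N_a^thres``.

    mode="convolution" (default)
        Each IList misses two independently with probability
        ``4 N_c^2 / N_L^2`` (Eqs for ``p1`` and ``P(2, N_c)``); the count is
        the resulting convolution of Bernoulli distributions.
    mode="placement"
        The two rare positions are drawn explicitly and misses are counted
        through the actual top subsets, retaining the correlation between
        ILists induced by the shared placement.

    Returns ``(xi, standard_error)``.
    """
    if n_draws < 1_000:
        import warnings

        warnings.warn("fewer than 1000 draws: Xi_context estimate will be noisy")
    rng = np.random.default_rng() if rng is None else rng
    thres = solve_activation_threshold(params)
    if thres == 0:
        return 1.0, 0.0
    n_l = params.n_ligands
    block = n_l // 2
    half = block // 2
    top_pb = params.n_top // 2
    n_lists = params.n_ilists

    hits = 0
    # draws are grouped in population realizations to amortize construction
    group = 128
    done = 0
    while done < n_draws:
        take = min(group, n_draws - done)
        if n_c_values is not None:
            nc = np.asarray(n_c_values, dtype=int)
            if nc.shape != (n_lists,):
                raise ValueError("n_c_values must have one entry per distinct IList")
            s1 = s2 = None
        else:
            # random balanced per-block top subsets; N_c emergent
            s1 = np.stack([rng.choice(block, top_pb, replace=False) for _ in range(n_lists)])
            s2 = np.stack([rng.choice(block, top_pb, replace=False) for _ in range(n_lists)])
            nc = (s1 >= half).sum(axis=1) + (s2 < half).sum(axis=1)
        if mode == "convolution":
            p2 = (2.0 * nc / n_l) ** 2
            miss = rng.random((take, n_lists)) < p2[None, :]
            counts = miss.sum(axis=1)
        elif mode == "placement":
            if s1 is None:
                raise ValueError("placement mode requires explicit top subsets")
            a = rng.integers(half, block, size=take)   # rare slot in block 1, central half
            b = rng.integers(0, half, size=take)       # rare slot in block 2, central half
            in1 = (s1[None, :, :] == a[:, None, None]).any(axis=2)
            in2 = (s2[None, :, :] == b[:, None, None]).any(axis=2)
            counts = (in1 & in2).sum(axis=1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        hits += int((counts >= thres).sum())
        done += take
    xi = hits / n_draws
    se = math.sqrt(max(xi * (1 - xi), 1e-12) / n_draws)
    return xi, se


# ---------------------------------------------------------------------------
# Small-instance lifetime model (destabilization-pressure reciprocal)
# ---------------------------------------------------------------------------


@dataclass
class LifetimeModel:
    """Destabilizer counts and stationary frequencies for a toy instance.

    ``destabilizers[(k, p), (i, j)]`` counts the ways the conjugate or single
    cell ``kp`` can destabilize conjugate ``ij`` (0 when it cannot);
    ``frequencies[(k, p)]`` are the stationary occupation frequencies.  Null
    indices (``None``) denote non-conjugated cells.
    """

    destabilizers: dict = field(default_factory=dict)
    frequencies: dict = field(default_factory=dict)


def lifetime_estimate(model: LifetimeModel, pair) -> float:
    """Relative conjugation lifetime of ``pair``: reciprocal pressure.

    Returns ``math.inf`` when nothing can destabilize the pair.
    """
    denom = 0.0
    for kp, freq in model.frequencies.items():
        denom += model.destabilizers.get((kp, pair), 0) * freq
    if denom <= 0:
        return math.inf
    return 1.0 / denom
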