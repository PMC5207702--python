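"""Frequent/rare perception of real-valued ligands (tail-quantile mapping).

Every APC displays a real number; every T cell compresses that number into
one of two perceived signals, frequent (``F_i``) or rare (``R_i``).  T cell
``j`` carries a discrimination fraction ``v_j ~ Uniform(0, v_max)`` and a
side (left or right tail): APC ``i``'s value is perceived as rare when it
falls strictly beyond the ``v_j``-tail quantile of that APC's empirical
self distribution on the cell's side.  Cells with ``v_j = 0`` perceive rare
only for values outside the observed self range — they are pure
nonself/outlier detectors; cells with larger ``v_j`` watch the distribution
tails and enable abnormal-self detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelfDistribution",
    "PerceptionMap",
    "fit_self_distribution",
    "assign_discrimination",
]


@dataclass
class SelfDistribution:
    """Per-APC empirical value distributions over self samples.

    ``values`` is (n_samples, n_apcs), column-sorted; quantiles use linear
    interpolation of the empirical CDF.
    """

    values: np.ndarray

    @property
    def n_apcs(self) -> int:
        return self.values.shape[1]

    def quantile(self, q) -> np.ndarray:
        """Per-APC quantile(s); q scalar -> (n_apcs,), vector -> (len(q), n_apcs)."""
        return np.quantile(self.values, q, axis=0)


def fit_self_distribution(self_samples: np.ndarray) -> SelfDistribution:
    """Column-wise empirical distributions from a (samples x APCs) matrix."""
    values = np.asarray(self_samples, dtype=float)
    if values.ndim != 2:
        raise ValueError("self samples must form a 2-D (samples x APCs) matrix")
    if values.shape[0] < 2:
        raise ValueError("need at least two self samples")
    return SelfDistribution(np.sort(values, axis=0))


def assign_discrimination(
    n_tcells: int, v_max: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell (v_j, side): v_j ~ U(0, v_max), side ~ Bernoulli(1/2).

    side 0 = rare on the left tail, 1 = right tail.  ``v_max`` must stay
    below 0.5: rare must remain the minority perception.
    """
    if not 0 <= v_max < 0.5:
        raise ValueError("v_max must lie in [0, 0.5)")
    v = rng.uniform(0.0, v_max, size=n_tcells)
    side = (rng.random(n_tcells) < 0.5).astype(np.int8)
    return v, side


@dataclass
class PerceptionMap:
    """Per-(T cell, APC) thresholds realizing the tail-quantile perception."""

    v: np.ndarray            # (n_tcells,)
    side: np.ndarray         # (n_tcells,) 0=left, 1=right
    thr_low: np.ndarray      # (n_tcells, n_apcs) v_j-quantile
    thr_high: np.ndarray     # (n_tcells, n_apcs) (1-v_j)-quantile

    @classmethod
    def fit(
        cls,
        dist: SelfDistribution,
        n_tcells: int,
        v_max: float,
        rng: np.random.Generator,
    ) -> "PerceptionMap":
        v, side = assign_discrimination(n_tcells, v_max, rng)
        thr_low = dist.quantile(v)
        thr_high = dist.quantile(1.0 - v)
        return cls(v, side, thr_low, thr_high)

    def rare_matrix(self, sample: np.ndarray) -> np.ndarray:
        """(n_tcells, n_apcs) rare flags for one displayed configuration.

        Strict comparisons: a value exactly at the threshold stays frequent
        (conservative self-tolerance); values beyond the observed self range
        are rare for every cell watching that side.
        """
        x = np.asarray(sample, dtype=float)[None, :]
        left = x < self.thr_low
        right = x > self.thr_high
        side = self.side[:, None]
        return np.where(side == 0, left, right)

    def perceive(self, value: float, apc_index: int, tcell_j: int) -> bool:
        """True when T cell ``tcell_j`` perceives ``value`` on APC ``apc_index`` as rare."""
        if self.side[tcell_j] == 0:
            return bool(value < self.thr_low[tcell_j, apc_index])
        return bool(value > self.thr_high[tcell_j, apc_index])

    def to_json(self) -> dict:
        return {
            "v": self.v.tolist(),
            "side": self.side.tolist(),
            "thr_low": self.thr_low.tolist(),
            "thr_high": self.thr_high.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PerceptionMap":
        return cls(
            np.asarray(obj["v"], float),
            np.asarray(obj["side"], np.int8),
            np.asarray(obj["thr_low"], float),
            np.asarray(obj["thr_high"], float),
        )
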