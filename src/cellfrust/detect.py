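"""Calibration and detection: activation thresholds, response statistic, ROC.

Calibration runs the anergy-limited dynamics on self samples and records,
per APC ``i`` and sample ``s``, the number of conjugations lasting at least
the activation lifetime, ``c_{i,s}(tau_act)``.  The per-APC activation
threshold ``n_i^0`` is the ``f``-quantile of those counts taken from the top
(the value at 1-based position ``ceil(N_s * f)`` of the descending sort).

At detection time a sample's response aggregates the above-threshold
excesses, normalized by each APC's total conjugation turnover:

    R_s = sum_i (c_{i,s}(tau_act) - n_i^0) / c_{i,s}(0) * theta(c_{i,s} - n_i^0)

with theta the Heaviside step (theta(0) = 0: the count must strictly exceed
the threshold to contribute).  APCs with no turnover contribute nothing.
The true-positive rate at a fixed false-positive rate compares abnormal
responses against the empirical (1-FPR)-quantile of the self responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc

from .engine import Simulation

__all__ = [
    "CalibrationParams",
    "ActivationThresholds",
    "ResponseSet",
    "calibrate",
    "respond",
    "response_from_counts",
    "tpr_at_fpr",
    "roc_curve",
]


@dataclass
class CalibrationParams:
    """Anergy-limited window parameters shared by calibration and detection.

    ``w_c`` and ``tau_a`` are in protocol iterations.  One iteration is a
    sweep of 2N elementary pairwise contacts (each cell drawn once in
    expectation); with it the activation lifetime ``tau_act = 5`` sits in
    the ~8% upper tail of the self-configuration conjugation-lifetime
    distribution.  ``tau_act`` equals the anergy lifetime ``tau_a``: a
    conjugation anergy-capped at ``tau_a`` has duration >= ``tau_act`` and
    counts as long-lived.
    """

    w_c: int = 10_000
    tau_a: int = 5
    f: float = 0.1
    n_samples: int = 1000
    iteration_sweeps: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.f < 1:
            raise ValueError("f must lie strictly between 0 and 1")
        if min(self.w_c, self.tau_a, self.iteration_sweeps) <= 0:
            raise ValueError("w_c, tau_a and iteration_sweeps must be positive")

    @property
    def tau_act(self) -> int:
        return self.tau_a

    def contacts(self, n: int) -> int:
        """Elementary contacts per protocol iteration for an N-cell system."""
        return self.iteration_sweeps * 2 * n


@dataclass
class ActivationThresholds:
    """Per-APC long-conjugation count thresholds from self calibration."""

    n0: np.ndarray
    counts: np.ndarray | None = None  # (n_samples, n_apcs) calibration counts

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.n0, dtype=dtype)


def threshold_from_counts(counts: np.ndarray, f: float) -> np.ndarray:
    """Descending-sort quantile: value at 1-based position ceil(S*f)."""
    counts = np.asarray(counts)
    s = counts.shape[0]
    x = math.ceil(s * f)
    if x < 1:
        raise ValueError("too few calibration samples for quantile fraction f")
    ordered = np.sort(counts, axis=0)[::-1]
    return ordered[x - 1].copy()


def calibrate(
    sim: Simulation,
    self_samples,
    params: CalibrationParams,
) -> ActivationThresholds:
    """Run the anergy dynamics over self samples and set per-APC thresholds.

    ``self_samples`` yields perception inputs (boolean rare flags, per-cell
    rare matrices, or per-repertoire-member stacks) accepted by
    :meth:`cellfrust.engine.Simulation.run_window`.
    """
    unit = params.contacts(sim.n)
    rows = []
    n_seen = 0
    for rare in self_samples:
        counts = sim.run_window(
            rare,
            params.w_c * unit,
            tau_act=params.tau_act * unit,
            anergy_tau=params.tau_a * unit,
        )
        rows.append(counts.c_act)
        n_seen += 1
    if n_seen == 0:
        raise ValueError("calibration requires at least one self sample")
    counts = np.asarray(rows)
    return ActivationThresholds(threshold_from_counts(counts, params.f), counts)


def calibrate_batch(
    sim: Simulation, rare_stack, params: CalibrationParams
) -> ActivationThresholds:
    """Batched calibration over a stack of self samples (full connectivity)."""
    unit = params.contacts(sim.n)
    cact, _, _ = sim.run_windows(
        rare_stack, params.w_c * unit, params.tau_act * unit, params.tau_a * unit
    )
    if cact.shape[0] == 0:
        raise ValueError("calibration requires at least one self sample")
    return ActivationThresholds(threshold_from_counts(cact, params.f), cact)


def respond_batch(
    sim: Simulation,
    rare_stack,
    thresholds: ActivationThresholds | np.ndarray,
    params: CalibrationParams,
) -> np.ndarray:
    """Responses R_s for a stack of samples (full connectivity)."""
    unit = params.contacts(sim.n)
    cact, c0, _ = sim.run_windows(
        rare_stack, params.w_c * unit, params.tau_act * unit, params.tau_a * unit
    )
    n0 = thresholds.n0 if isinstance(thresholds, ActivationThresholds) else thresholds
    return np.array(
        [response_from_counts(cact[s], c0[s], n0) for s in range(cact.shape[0])]
    )


def response_from_counts(
    c_act: np.ndarray, c0: np.ndarray, thresholds: np.ndarray
) -> float:
    """Aggregate response from per-APC counts (pure arithmetic of the sum)."""
    n0 = np.asarray(thresholds)
    c_act = np.asarray(c_act, dtype=float)
    c0 = np.asarray(c0, dtype=float)
    excess = c_act - n0
    active = (excess > 0) & (c0 > 0)
    return float(np.sum(excess[active] / c0[active]))


def respond(
    sim: Simulation,
    rare,
    thresholds: ActivationThresholds | np.ndarray,
    params: CalibrationParams,
) -> float:
    """Response R_s of one sample under the calibrated thresholds."""
    unit = params.contacts(sim.n)
    counts = sim.run_window(
        rare,
        params.w_c * unit,
        tau_act=params.tau_act * unit,
        anergy_tau=params.tau_a * unit,
    )
    n0 = thresholds.n0 if isinstance(thresholds, ActivationThresholds) else thresholds
    return response_from_counts(counts.c_act, counts.c0, n0)


@dataclass
class ResponseSet:
    """Responses of labelled detection samples."""

    r_self: np.ndarray
    r_anom: np.ndarray

    def tpr_at_fpr(self, fpr: float) -> float:
        return tpr_at_fpr(self.r_self, self.r_anom, fpr)

    def roc(self):
        return roc_curve(self.r_self, self.r_anom)

    def auc(self) -> float:
        fpr, tpr = roc_curve(self.r_self, self.r_anom)
        return float(_sk_auc(fpr, tpr))


def tpr_at_fpr(r_self, r_anom, fpr: float) -> float:
    """Fraction of abnormal responses strictly above the self FPR-threshold.

    The self threshold is the value at 1-based position ``ceil(N_self*FPR)``
    of the descending-sorted self responses; ties do not count as
    detections (strict inequality).
    """
    if not 0 < fpr < 1:
        raise ValueError("fpr must lie strictly between 0 and 1")
    r_self = np.sort(np.asarray(r_self, dtype=float))[::-1]
    r_anom = np.asarray(r_anom, dtype=float)
    if r_self.size == 0 or r_anom.size == 0:
        raise ValueError("both labels must be present")
    x = math.ceil(len(r_self) * fpr)
    r_x = r_self[x - 1]
    return float(np.mean(r_anom > r_x))


def roc_curve(r_self, r_anom) -> tuple[np.ndarray, np.ndarray]:
    """ROC points over all observed response thresholds (monotone, 0..1)."""
    scores = np.concatenate([np.asarray(r_self, float), np.asarray(r_anom, float)])
    labels = np.concatenate([np.zeros(len(r_self)), np.ones(len(r_anom))])
    fpr, tpr, _ = _sk_roc(labels, scores)
    return fpr, tpr
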