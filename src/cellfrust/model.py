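"""Model/Results surface: a one-class detector fitted to self samples.

``CellularFrustration`` wraps the whole pipeline the way a statsmodels
model wraps an estimator: construct it from a matrix of self samples (one
row per configuration, one column per APC), call :meth:`fit` to run
repertoire education and calibration, and use the returned
:class:`CellularFrustrationResults` to score new samples, compute
TPR-at-FPR and ROC curves, and print a summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import (
    ActivationThresholds,
    CalibrationParams,
    ResponseSet,
    calibrate_batch,
    respond_batch,
)
from .education import EducationParams, EducationTrace, build_repertoire
from .engine import Population, Simulation
from .mapping import PerceptionMap, SelfDistribution, fit_self_distribution

__all__ = ["CellularFrustration", "CellularFrustrationResults"]


class CellularFrustration:
    """Frustration-based anomaly detector over real-valued sample rows.

    Parameters
    ----------
    self_samples : (n_samples, n_apcs) array
        Self configurations; column ``i`` is the value displayed by APC
        ``i``.  For the ordered families rows should already be sorted.
    v_max : float
        Upper bound of the per-cell discrimination fraction ``v_j``.
    education, calibration : parameter bundles
        See :class:`EducationParams` and :class:`CalibrationParams`.
    n_education_samples : int or None
        How many training rows cycle through APC presentation during
        education (None = all).
    """

    def __init__(
        self,
        self_samples: np.ndarray,
        v_max: float = 0.05,
        education: EducationParams | None = None,
        calibration: CalibrationParams | None = None,
        n_education_samples: int | None = None,
    ) -> None:
        self.self_samples = np.asarray(self_samples, dtype=float)
        if self.self_samples.ndim != 2:
            raise ValueError("self_samples must be 2-D (samples x APCs)")
        n = self.self_samples.shape[1]
        if n % 2:
            raise ValueError("the APC count must be even (two subtypes)")
        self.n = n
        self.v_max = v_max
        self.education = education or EducationParams()
        self.calibration = calibration or CalibrationParams()
        self.n_education_samples = n_education_samples

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CellularFrustration":
        return cls(df.to_numpy(dtype=float), **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(self, seed: int | np.random.Generator = 0) -> "CellularFrustrationResults":
        """Educate the repertoire and calibrate activation thresholds."""
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        dist = fit_self_distribution(self.self_samples)
        n_edu = self.n_education_samples or self.self_samples.shape[0]
        edu_rows = self.self_samples[:n_edu]

        maps: list[PerceptionMap] = []
        pops: list[Population] = []
        traces: list[EducationTrace] = []
        for _ in range(self.education.n_populations):
            pmap = PerceptionMap.fit(dist, self.n, self.v_max, rng)
            stream = np.stack([pmap.rare_matrix(row) for row in edu_rows])
            single = EducationParams(
                self.education.w_tau,
                self.education.t_s,
                self.education.stop_window,
                1,
                self.education.max_iter,
            )
            pop_list, trace_list = build_repertoire(self.n, stream, single, rng)
            pops.extend(pop_list)
            traces.extend(trace_list)
            maps.append(pmap)

        sim = Simulation(pops, rng)
        cal_rows = self.self_samples[: self.calibration.n_samples]
        if len(cal_rows) == 0:
            raise ValueError("no calibration samples available")
        thresholds = calibrate_batch(
            sim,
            np.stack([self._rare_stack(maps, row) for row in cal_rows]),
            self.calibration,
        )
        return CellularFrustrationResults(
            model=self,
            distribution=dist,
            perception_maps=maps,
            repertoire=pops,
            traces=traces,
            thresholds=thresholds,
            sim=sim,
        )

    @staticmethod
    def _rare_stack(maps: list[PerceptionMap], row: np.ndarray) -> np.ndarray:
        return np.stack([m.rare_matrix(row) for m in maps])


@dataclass
class CellularFrustrationResults:
    """Fitted repertoire, thresholds and scoring methods."""

    model: CellularFrustration
    distribution: SelfDistribution
    perception_maps: list[PerceptionMap]
    repertoire: list[Population]
    traces: list[EducationTrace]
    thresholds: ActivationThresholds
    sim: Simulation = field(repr=False)

    # -- scoring ----------------------------------------------------------
    def respond(self, samples: np.ndarray, chunk: int = 128) -> np.ndarray:
        """Response R_s per row of ``samples`` (larger = more anomalous)."""
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        out = np.empty(len(samples))
        for lo in range(0, len(samples), chunk):
            rows = samples[lo:lo + chunk]
            stack = np.stack(
                [CellularFrustration._rare_stack(self.perception_maps, row) for row in rows]
            )
            out[lo:lo + len(rows)] = respond_batch(
                self.sim, stack, self.thresholds, self.model.calibration
            )
        return out

    def evaluate(self, self_eval: np.ndarray, anom_eval: np.ndarray) -> ResponseSet:
        return ResponseSet(self.respond(self_eval), self.respond(anom_eval))

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        taus = [t.final_tau for t in self.traces]
        iters = [t.total_iterations for t in self.traces]
        elims = [int(t.elim_counts.sum()) for t in self.traces]
        lines = [
            "Cellular frustration detector",
            "=" * 46,
            f"APCs per type:            {m.n}",
            f"Self samples (fit):       {m.self_samples.shape[0]}",
            f"v_max:                    {m.v_max:g}",
            f"repertoire size:          {len(self.repertoire)}",
            f"education w_tau / T_s:    {m.education.w_tau} / {m.education.t_s}",
            f"final tau_n per member:   {taus}",
            f"education iterations:     {iters}",
            f"eliminations per member:  {elims}",
            f"calibration W_c / tau_A:  {m.calibration.w_c} / {m.calibration.tau_a}",
            f"calibration samples / f:  {self.thresholds.counts.shape[0]} / {m.calibration.f:g}",
            f"mean activation threshold n_i^0: {float(np.mean(self.thresholds.n0)):.2f}",
        ]
        return "\n".join(lines)
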