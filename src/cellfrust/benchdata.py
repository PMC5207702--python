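"""Synthetic benchmark families and classical location-test baselines.

Three sample families probe the detector against textbook statistics:

* ``gaussian_ordered`` — rows of n=80 sorted draws from Normal(50, 10);
  abnormal rows shift the mean by ``delta`` (one side per dataset, both
  sides testable).  The matched classical tests are the known-sigma z test
  and the one-sample KS test.
* ``lognormal_ordered`` — lognormal rows with the same mean and standard
  deviation (moment-matched), a heavy-tailed regime where the z test loses
  power.
* ``gaussian_unordered`` — unsorted rows; abnormal rows deviate each
  element independently by ±delta, a multivariate pattern with an unshifted
  pooled marginal mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc

__all__ = [
    "DatasetSpec",
    "BenchmarkData",
    "gen_gaussian_ordered",
    "gen_lognormal_ordered",
    "gen_gaussian_unordered",
    "make_benchmark",
    "generator_for",
    "lognormal_params",
    "location_test_baseline",
    "baseline_statistics",
    "baseline_roc",
]


@dataclass
class DatasetSpec:
    """Benchmark geometry and distribution parameters."""

    n_elements: int = 80
    mu: float = 50.0
    sigma: float = 10.0
    delta: float = 2.0
    sign: int = +1              # side of the mean shift for ordered families
    family: str = "gaussian_ordered"
    n_train: int = 1000
    n_self_eval: int = 1000
    n_anom_eval: int = 1000

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.family not in (
            "gaussian_ordered",
            "lognormal_ordered",
            "gaussian_unordered",
        ):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class BenchmarkData:
    """Train (self), self-evaluation and abnormal-evaluation matrices."""

    spec: DatasetSpec
    train: np.ndarray
    self_eval: np.ndarray
    anom_eval: np.ndarray


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) giving a lognormal with target moments."""
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal moments must be positive")
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _rows_gaussian(n_rows, spec, mu, rng, ordered=True):
    x = rng.normal(mu, spec.sigma, size=(n_rows, spec.n_elements))
    return np.sort(x, axis=1) if ordered else x


def _rows_lognormal(n_rows, spec, mean, rng):
    mu_ln, s_ln = lognormal_params(mean, spec.sigma)
    x = rng.lognormal(mu_ln, s_ln, size=(n_rows, spec.n_elements))
    return np.sort(x, axis=1)


def gen_gaussian_ordered(
    spec: DatasetSpec, rng: np.random.Generator, anomalous: bool = False, n_rows: int | None = None
) -> np.ndarray:
    """Sorted Gaussian rows; abnormal rows shift the mean by sign*delta."""
    mu = spec.mu + (spec.sign * spec.delta if anomalous else 0.0)
    n_rows = (spec.n_anom_eval if anomalous else spec.n_train) if n_rows is None else n_rows
    return _rows_gaussian(n_rows, spec, mu, rng, ordered=True)


def gen_lognormal_ordered(
    spec: DatasetSpec, rng: np.random.Generator, anomalous: bool = False, n_rows: int | None = None
) -> np.ndarray:
    """Sorted lognormal rows, moment-matched to (mu, sigma)."""
    mean = spec.mu + (spec.sign * spec.delta if anomalous else 0.0)
    n_rows = (spec.n_anom_eval if anomalous else spec.n_train) if n_rows is None else n_rows
    return _rows_lognormal(n_rows, spec, mean, rng)


def gen_gaussian_unordered(
    spec: DatasetSpec, rng: np.random.Generator, anomalous: bool = False, n_rows: int | None = None
) -> np.ndarray:
    """Unsorted Gaussian rows; abnormal elements deviate by ±delta i.i.d."""
    n_rows = (spec.n_anom_eval if anomalous else spec.n_train) if n_rows is None else n_rows
    x = rng.normal(spec.mu, spec.sigma, size=(n_rows, spec.n_elements))
    if anomalous:
        signs = rng.choice([-1.0, 1.0], size=x.shape)
        x = x + signs * spec.delta
    return x


def generator_for(family: str):
    """Row generator for a benchmark family."""
    return _GEN[family]


_GEN = {
    "gaussian_ordered": gen_gaussian_ordered,
    "lognormal_ordered": gen_lognormal_ordered,
    "gaussian_unordered": gen_gaussian_unordered,
}


def make_benchmark(spec: DatasetSpec, rng: np.random.Generator) -> BenchmarkData:
    gen = _GEN[spec.family]
    return BenchmarkData(
        spec=spec,
        train=gen(spec, rng, False, spec.n_train),
        self_eval=gen(spec, rng, False, spec.n_self_eval),
        anom_eval=gen(spec, rng, True, spec.n_anom_eval),
    )


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------


def location_test_baseline(
    sample: np.ndarray,
    mu0: float = 50.0,
    sigma_known: float = 10.0,
    kind: str = "t_like",
) -> tuple[float, float]:
    """Two-sided one-sample location test against Normal(mu0, sigma).

    kind="t_like": the known-sigma z form, statistic sqrt(n)(mean-mu0)/sigma.
    kind="ks": one-sample Kolmogorov-Smirnov vs the reference CDF.
    Returns (statistic, p-value).
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("sample must be non-empty")
    if kind == "t_like":
        z = math.sqrt(x.size) * (x.mean() - mu0) / sigma_known
        return z, 2.0 * stats.norm.sf(abs(z))
    if kind == "ks":
        res = stats.kstest(x, stats.norm(mu0, sigma_known).cdf)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown kind {kind!r}")


def baseline_statistics(
    samples: np.ndarray, mu0: float = 50.0, sigma_known: float = 10.0, kind: str = "t_like"
) -> np.ndarray:
    """Row-wise baseline statistics (absolute value for two-sided scoring)."""
    out = np.array(
        [location_test_baseline(row, mu0, sigma_known, kind)[0] for row in samples]
    )
    return np.abs(out) if kind == "t_like" else out


def baseline_roc(
    statistics_self: np.ndarray, statistics_anom: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over two-sided statistic magnitudes; returns (fpr, tpr, auc)."""
    scores = np.concatenate([np.abs(statistics_self), np.abs(statistics_anom)])
    labels = np.concatenate(
        [np.zeros(len(statistics_self)), np.ones(len(statistics_anom))]
    )
    fpr, tpr, _ = _sk_roc(labels, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def spec_with_delta(spec: DatasetSpec, delta: float, sign: int | None = None) -> DatasetSpec:
    return replace(spec, delta=delta, sign=spec.sign if sign is None else sign)
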