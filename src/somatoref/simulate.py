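"""Simulated healthy reference distributions for the somatosensory battery.

Healthy-control performance on TOJ/TOJc/DUR is positively skewed and
strictly positive, so a normal reference built from the pooled mean/SD
would be misleading.  Instead a gamma distribution is parameterised by
method of moments from the pooled moments —

    shape = mean^2 / sd^2,        rate = mean / sd^2

— and healthy reference samples are drawn from it.  Repeated small-sample
simulation (by default 100 samples of 45 observations, the paired-cohort
size) yields the "adjusted" pooled median and average interquartile
range, the skew-appropriate healthy summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._rng import substream

__all__ = [
    "PUBLISHED_POOLED",
    "GammaParams",
    "AdjustedSummary",
    "gamma_from_moments",
    "draw_reference_sample",
    "adjusted_pooled_summary",
    "reference_params",
]

#: Published pooled healthy reference mean/SD in ms per measure.  These are
#: the values the downstream analyses consume as reference inputs (the
#: independently recomputed pooled SDs for TOJ and DUR differ slightly;
#: see pooling module and docs/methods.md).
PUBLISHED_POOLED: dict[str, tuple[float, float]] = {
    "TOJ": (34.0, 17.0),
    "TOJc": (92.6, 40.4),
    "DUR": (61.5, 27.9),
}


@dataclass(frozen=True)
class GammaParams:
    """Gamma distribution in shape/rate form (rate in 1/ms).

    mean = shape/rate, variance = shape/rate^2.
    """

    shape: float
    rate: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError(
                f"shape and rate must be positive, got {self.shape}, {self.rate}"
            )

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def sd(self) -> float:
        return np.sqrt(self.shape) / self.rate

    @property
    def scale(self) -> float:
        return 1.0 / self.rate

    def quantile(self, q) -> float | np.ndarray:
        """Analytic quantile(s) via the inverse regularised incomplete gamma."""
        return stats.gamma.ppf(q, self.shape, scale=self.scale)

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))


@dataclass(frozen=True)
class AdjustedSummary:
    """Simulation-adjusted healthy summary for one measure."""

    measure: str
    pooled_median: float
    average_iqr: tuple[float, float]
    reps: int
    n_per_rep: int
    seed: int

    def __post_init__(self):
        lo, hi = self.average_iqr
        if not (0 < lo <= self.pooled_median <= hi):
            raise ValueError(
                f"{self.measure}: inconsistent summary "
                f"median={self.pooled_median}, IQR=({lo}, {hi})"
            )


def gamma_from_moments(mean: float, sd: float) -> GammaParams:
    """Method-of-moments gamma parameters from a mean and SD (both ms)."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    return GammaParams(shape=mean**2 / sd**2, rate=mean / sd**2)


def reference_params(measure: str) -> GammaParams:
    """Gamma parameters of the published pooled healthy reference."""
    mean, sd = PUBLISHED_POOLED[measure]
    return gamma_from_moments(mean, sd)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_reference_sample(params: GammaParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` healthy reference values (ms, strictly positive).

    ``seed`` may be an integer or a numpy Generator; a fixed integer seed
    reproduces the identical sample.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = _as_rng(seed)
    return rng.gamma(shape=params.shape, scale=params.scale, size=int(n))


def adjusted_pooled_summary(
    params: GammaParams,
    n_per_rep: int = 45,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    measure: str = "",
    median_pooling: str = "concat",
) -> AdjustedSummary:
    """Approximate the reference median and average IQR by simulation.

    Draws ``reps`` samples of ``n_per_rep`` observations.  The pooled
    median is, by default, the median of all reps*n_per_rep draws
    concatenated (``median_pooling="concat"``; the lower-variance
    reading).  ``median_pooling="median_of_medians"`` instead takes the
    median of the per-sample medians; both agree within Monte-Carlo
    error.  The average IQR is always the per-sample (Q1, Q3) averaged
    over reps.  Quartiles use linear interpolation between order
    statistics (numpy's default convention).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if n_per_rep < 2:
        raise ValueError(f"n_per_rep must be >= 2, got {n_per_rep}")
    if median_pooling not in ("concat", "median_of_medians"):
        raise ValueError(f"unknown median_pooling {median_pooling!r}")
    rng = _as_rng(seed)
    draws = rng.gamma(
        shape=params.shape, scale=params.scale, size=(int(reps), int(n_per_rep))
    )
    q1s = np.quantile(draws, 0.25, axis=1)
    q3s = np.quantile(draws, 0.75, axis=1)
    if median_pooling == "concat":
        pooled_median = float(np.median(draws))
    else:
        pooled_median = float(np.median(np.median(draws, axis=1)))
    return AdjustedSummary(
        measure=measure,
        pooled_median=pooled_median,
        average_iqr=(float(np.mean(q1s)), float(np.mean(q3s))),
        reps=int(reps),
        n_per_rep=int(n_per_rep),
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )


def measure_rng(master_seed: int, measure: str, stage: str = "reference") -> np.random.Generator:
    """Per-measure substream so each measure is independently reproducible."""
    return substream(master_seed, stage, measure)
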