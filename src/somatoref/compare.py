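"""Rank-based comparisons against simulated healthy references.

Wraps the standard nonparametric tests (Mann-Whitney U, Wilcoxon
signed-rank, Kruskal-Wallis) with explicit, documented exact-versus-
approximate switching, adds Dunn's post hoc pairwise comparison, and
implements the repeated simulated-reference experiment: because any
single simulated healthy sample might be unrepresentative, the
patient-versus-reference Mann-Whitney test is repeated against freshly
simulated reference samples (100 by default) and the percentage of
significant comparisons is reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .simulate import GammaParams, draw_reference_sample

__all__ = [
    "DegenerateDataError",
    "ComparisonExperiment",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "dunn_posthoc",
    "repeated_reference_comparison",
]

#: Exact-test cutoffs (desk-scale enumeration limits): Mann-Whitney exact
#: when the combined sample size is at most this and there are no ties;
#: Wilcoxon exact for at most this many non-zero pairs without tied
#: absolute differences.  Above them, tie-corrected normal approximations
#: with continuity correction.
MANN_WHITNEY_EXACT_MAX = 20
WILCOXON_EXACT_MAX = 15


class DegenerateDataError(ValueError):
    """Raised when the data admit no test (e.g. all paired differences zero)."""


@dataclass
class ComparisonExperiment:
    """Result of a repeated simulated-reference comparison."""

    measure: str
    timepoint: str
    reps: int
    p_values: list[float]
    alpha: float
    seed: int
    pct_significant: float = field(init=False)

    def __post_init__(self):
        if len(self.p_values) != self.reps:
            raise ValueError("one p-value per repetition required")
        if any(not 0 <= p <= 1 for p in self.p_values):
            raise ValueError("p-values must lie in [0, 1]")
        self.pct_significant = (
            100.0 * sum(p < self.alpha for p in self.p_values) / self.reps
        )


def _clean(sample, name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    return arr


def mann_whitney_u(
    x, y, exact_max: int = MANN_WHITNEY_EXACT_MAX, continuity: bool = True
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is small
    (``exact_max``, default 20) and the data are tie-free; otherwise the
    tie-corrected normal approximation (continuity-corrected by default).
    Returns (U of the first sample, two-sided p).
    """
    x = _clean(x, "first")
    y = _clean(y, "second")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    pre, post, exact_max: int = WILCOXON_EXACT_MAX, continuity: bool = True
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences of exactly zero are dropped before ranking (the classic
    convention); if every difference is zero the input is degenerate and
    an error is raised rather than a p-value fabricated.  Exact null
    distribution for at most ``exact_max`` tie-free non-zero pairs.
    Returns (W = smaller signed-rank sum, two-sided p).
    """
    pre = _clean(pre, "pre")
    post = _clean(post, "post")
    if len(pre) != len(post):
        raise ValueError("paired samples must have equal length")
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (d.size <= exact_max and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=continuity, method=method
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test (tie-corrected, chi-square p on k-1 df)."""
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    arrs = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(np.unique(np.concatenate(arrs))) == 1:
        return 0.0, 1.0  # every observation tied: no evidence of any difference
    res = stats.kruskal(*arrs)
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(groups, labels=None, adjust: str | None = None) -> pd.DataFrame:
    """Dunn's post hoc pairwise z tests following a Kruskal-Wallis test.

    All observations are ranked jointly (ties as midranks); the pairwise
    statistic is

        z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )

    with T = sum over tie groups of (t^3 - t).  P-values are two-sided
    normal and unadjusted by default; ``adjust`` may be "bonferroni" or
    "holm".
    """
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    arrs = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    pooled = np.concatenate(arrs)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks, sizes = [], []
    start = 0
    for a in arrs:
        mean_ranks.append(float(np.mean(ranks[start : start + len(a)])))
        sizes.append(len(a))
        start += len(a)
    rows = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        se = np.sqrt(var_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_i": labels[i], "group_j": labels[j], "z": z, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p"], method=adjust)[1]
    return df


def repeated_reference_comparison(
    patient_values,
    params: GammaParams,
    reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    measure: str = "",
    timepoint: str = "initial",
) -> ComparisonExperiment:
    """Repeat the patient-versus-simulated-reference Mann-Whitney test.

    Each repetition draws a fresh healthy reference sample of the same
    size as the patient sample from ``params`` and runs a two-sided
    Mann-Whitney U test.  The distribution of the ``reps`` p-values and
    the percentage below ``alpha`` quantify how consistently the patient
    sample differs from healthy reference performance.
    """
    patient = _clean(patient_values, "patient")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = substream(seed, "reference-comparison", measure, timepoint)
    p_values = []
    for _ in range(reps):
        ref = draw_reference_sample(params, len(patient), rng)
        _, p = mann_whitney_u(patient, ref)
        p_values.append(p)
    return ComparisonExperiment(
        measure=measure,
        timepoint=timepoint,
        reps=reps,
        p_values=p_values,
        alpha=alpha,
        seed=seed,
    )
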