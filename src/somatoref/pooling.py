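"""Pooling of published healthy-control summaries into reference moments.

Clinicians rarely have a locally recruited control group for the Brain
Gauge somatosensory battery (temporal order judgement TOJ, TOJ with a
concurrent confounding stimulus TOJc, and duration discrimination DUR,
all in milliseconds).  This module combines group summaries published
across independent studies into a single healthy reference mean/SD per
measure, following the Cochrane Handbook conventions for combining
groups: standard errors and confidence intervals are first transformed
to standard deviations, then groups are pooled as if their raw samples
had been concatenated.

The packaged fixture ``data/reference_studies.csv`` carries the published
per-study values; studies that reported standard errors are stored as
such (the transform runs here), while the one study that reported
confidence intervals is stored with its already-transformed SD because
the interval bounds were not published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MEASURES",
    "StudySummary",
    "PooledReference",
    "se_to_sd",
    "ci_to_sd",
    "pool_mean",
    "pool_sd",
    "build_reference_table",
    "load_reference_studies",
    "read_studies_csv",
    "pooled_table_frame",
]

#: Canonical measure labels, in reporting order.
MEASURES = ("TOJ", "TOJc", "DUR")

_CANON = {m.lower(): m for m in MEASURES}


def canonical_measure(label: str) -> str:
    """Map a measure label to its canonical form, case-insensitively."""
    try:
        return _CANON[str(label).strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown measure {label!r}; expected one of {MEASURES}"
        ) from None


@dataclass(frozen=True)
class StudySummary:
    """One published group's summary of one somatosensory measure.

    ``dispersion_value`` is an SD or SE in ms depending on
    ``dispersion_kind``; for kind ``"CI"`` the interval is given by
    ``ci_lower``/``ci_upper`` (ms) at confidence ``ci_level``.
    """

    study_label: str
    measure: str
    n: int
    mean: float
    dispersion_kind: str  # "SD" | "SE" | "CI"
    dispersion_value: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float = 0.95

    def __post_init__(self):
        object.__setattr__(self, "measure", canonical_measure(self.measure))
        kind = self.dispersion_kind.upper()
        if kind not in ("SD", "SE", "CI"):
            raise ValueError(f"unknown dispersion kind {self.dispersion_kind!r}")
        object.__setattr__(self, "dispersion_kind", kind)
        if self.n < 1:
            raise ValueError(f"{self.study_label}: n must be positive, got {self.n}")
        if kind in ("SE", "CI") and self.n < 2:
            raise ValueError(
                f"{self.study_label}: n >= 2 required to transform {kind} to SD"
            )
        if kind in ("SD", "SE"):
            if self.dispersion_value is None or self.dispersion_value < 0:
                raise ValueError(
                    f"{self.study_label}: non-negative dispersion_value required"
                )
        else:
            if self.ci_lower is None or self.ci_upper is None:
                raise ValueError(f"{self.study_label}: CI requires bounds")
            if not (self.ci_lower <= self.mean <= self.ci_upper):
                raise ValueError(
                    f"{self.study_label}: CI [{self.ci_lower}, {self.ci_upper}] "
                    f"must bracket the mean {self.mean}"
                )

    @property
    def sd(self) -> float:
        """The study SD in ms, transformed from the reported dispersion."""
        if self.dispersion_kind == "SD":
            return float(self.dispersion_value)
        if self.dispersion_kind == "SE":
            return se_to_sd(self.dispersion_value, self.n)
        return ci_to_sd(self.ci_lower, self.ci_upper, self.n, self.ci_level)


@dataclass
class PooledReference:
    """Pooled healthy reference moments for one measure.

    ``adjusted_median``/``adjusted_iqr`` are filled later by the gamma
    reference simulation (skew-appropriate summaries).
    """

    measure: str
    pooled_n: int
    pooled_mean: float
    pooled_sd: float
    adjusted_median: float | None = None
    adjusted_iqr: tuple[float, float] | None = None
    studies: list[StudySummary] = field(default_factory=list, repr=False)


def se_to_sd(se: float, n: int) -> float:
    """Transform a standard error of the mean back to a sample SD.

    SD = SE * sqrt(n).
    """
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if se < 0:
        raise ValueError(f"standard error must be non-negative, got {se}")
    return float(se) * np.sqrt(n)


def ci_to_sd(lower: float, upper: float, n: int, level: float = 0.95) -> float:
    """Transform a two-sided t confidence interval for the mean to an SD.

    SD = sqrt(n) * (upper - lower) / (2 * t_crit), with the t critical
    value at the given two-sided level on n-1 degrees of freedom (the
    Cochrane small-sample refinement of the normal 3.92 divisor).
    """
    if n < 2:
        raise ValueError(f"n >= 2 required for a CI transform, got {n}")
    if upper < lower:
        raise ValueError(f"upper < lower: [{lower}, {upper}]")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    if upper == lower:
        return 0.0
    t_crit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return np.sqrt(n) * (upper - lower) / (2.0 * t_crit)


def pool_mean(groups: Sequence[tuple[int, float]]) -> float:
    """Sample-size-weighted mean of group means (order-invariant)."""
    if len(groups) == 0:
        raise ValueError("cannot pool an empty group list")
    ns = np.array([g[0] for g in groups], dtype=float)
    ms = np.array([g[1] for g in groups], dtype=float)
    if np.any(ns < 1):
        raise ValueError("all group sizes must be >= 1")
    return float(np.sum(ns * ms) / np.sum(ns))


def pool_sd(groups: Sequence[tuple[int, float, float]]) -> float:
    """SD of the notional concatenation of the summarised groups.

    Generalised Cochrane combination (reduces to the Handbook's
    Table 7.7.a formula for two groups):

        sqrt( [ sum (n_i - 1) s_i^2 + sum n_i (m_i - M)^2 ] / (sum n_i - 1) )

    with M the pooled mean.  Equals, exactly, the (n-1)-denominator SD of
    the concatenated raw samples whose summaries were supplied.
    """
    if len(groups) == 0:
        raise ValueError("cannot pool an empty group list")
    ns = np.array([g[0] for g in groups], dtype=float)
    ms = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("all group sizes must be >= 2 to pool SDs")
    if np.any(sds < 0):
        raise ValueError("SDs must be non-negative")
    big_m = np.sum(ns * ms) / np.sum(ns)
    num = np.sum((ns - 1) * sds**2) + np.sum(ns * (ms - big_m) ** 2)
    return float(np.sqrt(num / (np.sum(ns) - 1)))


def build_reference_table(studies: Iterable[StudySummary]) -> list[PooledReference]:
    """Pool per-study summaries into one healthy reference per measure.

    Dispersions are transformed to SDs per study, then groups are pooled
    by concatenation.  Measures with no contributing study are omitted;
    output follows the canonical TOJ, TOJc, DUR order.
    """
    by_measure: dict[str, list[StudySummary]] = {m: [] for m in MEASURES}
    for s in studies:
        by_measure[s.measure].append(s)
    out = []
    for measure in MEASURES:
        grp = by_measure[measure]
        if not grp:
            continue
        triples = [(s.n, s.mean, s.sd) for s in grp]
        out.append(
            PooledReference(
                measure=measure,
                pooled_n=int(sum(s.n for s in grp)),
                pooled_mean=pool_mean([(n, m) for n, m, _ in triples]),
                pooled_sd=pool_sd(triples),
                studies=list(grp),
            )
        )
    return out


def _studies_from_frame(df: pd.DataFrame, source: str) -> list[StudySummary]:
    required = {"study_label", "measure", "n", "mean", "dispersion_kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source}: missing columns {sorted(missing)}")
    studies = []
    for idx, row in df.iterrows():
        kind = str(row["dispersion_kind"]).upper()
        kwargs = dict(
            study_label=str(row["study_label"]),
            measure=str(row["measure"]),
            n=int(row["n"]),
            mean=float(row["mean"]),
            dispersion_kind=kind,
        )
        if kind == "CI":
            kwargs.update(
                ci_lower=float(row["ci_lower"]),
                ci_upper=float(row["ci_upper"]),
                ci_level=float(row.get("ci_level", 0.95) or 0.95),
            )
        else:
            kwargs["dispersion_value"] = float(row["dispersion_value"])
        try:
            studies.append(StudySummary(**kwargs))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source}, row {idx}: {exc}") from exc
    return studies


def read_studies_csv(path) -> list[StudySummary]:
    """Read a study-summary table from CSV (documented column schema)."""
    return _studies_from_frame(pd.read_csv(path), str(path))


def load_reference_studies() -> list[StudySummary]:
    """Load the packaged table of published healthy-control summaries."""
    ref = resources.files("somatoref").joinpath("data/reference_studies.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    return _studies_from_frame(df, "packaged reference_studies.csv")


def pooled_table_frame(refs: Sequence[PooledReference]) -> pd.DataFrame:
    """Tabulate pooled references (one row per measure) for CSV output."""
    rows = []
    for r in refs:
        rows.append(
            {
                "measure": r.measure,
                "pooled_n": r.pooled_n,
                "pooled_mean": r.pooled_mean,
                "pooled_sd": r.pooled_sd,
                "adjusted_median": r.adjusted_median,
                "adjusted_q1": r.adjusted_iqr[0] if r.adjusted_iqr else None,
                "adjusted_q3": r.adjusted_iqr[1] if r.adjusted_iqr else None,
            }
        )
    return pd.DataFrame(rows)
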