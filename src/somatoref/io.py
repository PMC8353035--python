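"""Run configuration, cohort file I/O, and end-to-end pipeline orchestration.

A single master seed drives every stochastic stage through named
substreams, so a rerun with the same configuration is bit-identical and
each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    PatientRecord,
    generate_cohort,
    generate_discharge,
    records_to_frame,
)
from .compare import repeated_reference_comparison, wilcoxon_signed_rank
from .discriminate import loocv_discriminate
from .pooling import (
    build_reference_table,
    load_reference_studies,
    pooled_table_frame,
    read_studies_csv,
)
from .simulate import (
    PUBLISHED_POOLED,
    adjusted_pooled_summary,
    gamma_from_moments,
    reference_params,
)
from ._rng import substream
from .trees import BG_FEATURES, COMBINED_FEATURES, derived_features, loocv_tree

__all__ = ["RunConfig", "read_cohort", "write_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)

_COHORT_COLUMNS = [
    "id", "sex", "age", "sport", "trajectory",
    "days_to_initial", "days_to_asymptomatic",
    "toj", "tojc", "dur", "pst", "sss",
    "discharge_toj", "discharge_tojc", "discharge_dur",
    "discharge_pst", "discharge_sss",
]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    seed: int = 0
    out_dir: str = "results"
    studies_path: str | None = None  # None -> packaged reference table
    cohort_path: str | None = None  # None -> synthetic cohort
    reps: int = 100
    n_per_rep: int = 45
    alpha: float = 0.05
    use_published_pooled: bool = True  # reference moments fed downstream
    cp_grid_size: int = 10
    verbosity: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.cp_grid_size < 1:
            raise ValueError("cp grid must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_cohort(records, path) -> None:
    """Write the cohort to CSV (wide layout, one row per participant)."""
    df = records_to_frame(records)
    for col in _COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df[_COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; schema violations name the row."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty cohort file")
        return []
    if df.empty:
        warnings.warn(f"{path}: empty cohort file")
        return []
    mandatory = ["id", "sex", "trajectory", "toj", "tojc", "dur", "pst", "sss"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    records = []
    for idx, row in df.iterrows():
        def opt(col, cast=float):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else cast(v)

        try:
            rec = PatientRecord(
                id=str(row["id"]),
                sex=str(row["sex"]),
                age=opt("age") or 0.0,
                sport=str(row.get("sport", "")),
                trajectory=str(row["trajectory"]),
                days_to_initial=opt("days_to_initial") or 0.0,
                days_to_asymptomatic=opt("days_to_asymptomatic"),
                toj=float(row["toj"]),
                tojc=float(row["tojc"]),
                dur=float(row["dur"]),
                pst=int(row["pst"]),
                sss=int(row["sss"]),
                discharge_toj=opt("discharge_toj"),
                discharge_tojc=opt("discharge_tojc"),
                discharge_dur=opt("discharge_dur"),
                discharge_pst=opt("discharge_pst", int),
                discharge_sss=opt("discharge_sss", int),
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {idx + 2}: {exc}") from exc
        records.append(rec)
    return records


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def run_pipeline(config: RunConfig, cohort_config: CohortConfig | None = None) -> dict:
    """Execute the full analysis and write the results bundle.

    Stages, in order: literature pooling -> gamma reference simulation
    (adjusted medians/IQRs) -> synthetic cohort (or cohort file) ->
    LOOCV logistic discrimination per measure -> LOOCV-tuned
    classification trees (both feature sets) -> repeated
    simulated-reference comparisons at both timepoints plus paired
    Wilcoxon tests.  Returns the bundle as a dict and writes CSV/JSON
    artefacts plus a manifest to ``config.out_dir``.
    """
    config.validate()
    logging.basicConfig(level=config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- pooling -----------------------------------------------------------
    studies = (
        read_studies_csv(config.studies_path)
        if config.studies_path
        else load_reference_studies()
    )
    refs = build_reference_table(studies)

    # Reference moments consumed downstream: the published pooled values by
    # default (two printed SDs differ slightly from the recomputed ones).
    if config.use_published_pooled:
        moments = dict(PUBLISHED_POOLED)
    else:
        moments = {r.measure: (r.pooled_mean, r.pooled_sd) for r in refs}

    # --- reference simulation ---------------------------------------------
    for r in refs:
        params = gamma_from_moments(*moments[r.measure])
        summ = adjusted_pooled_summary(
            params,
            n_per_rep=config.n_per_rep,
            reps=config.reps,
            seed=substream(seed, "reference", r.measure),
            measure=r.measure,
        )
        r.adjusted_median = summ.pooled_median
        r.adjusted_iqr = summ.average_iqr
    pooled_df = pooled_table_frame(refs)
    pooled_df.to_csv(out / "pooled_reference.csv", index=False)

    # --- cohort ------------------------------------------------------------
    if config.cohort_path:
        records = read_cohort(config.cohort_path)
    else:
        cc = cohort_config or CohortConfig()
        records = generate_cohort(cc, seed=seed)
        records = generate_discharge(records, cc, seed=seed)
    write_cohort(records, out / "cohort.csv")
    frame = records_to_frame(records)
    paired = frame[frame["discharge_toj"].notna()]

    measure_params = {m: gamma_from_moments(*moments[m]) for m in moments}

    # --- discrimination ----------------------------------------------------
    discrimination = {}
    fold_frames = []
    for m in ("TOJ", "TOJc", "DUR"):
        col = m.lower()
        cv = loocv_discriminate(
            frame[col].to_numpy(), measure_params[m], seed=seed, measure=m
        )
        discrimination[m] = {
            "sensitivity": cv.sensitivity,
            "specificity": cv.specificity,
            "ppv": cv.ppv,
            "npv": cv.npv,
            "pct_correct": cv.pct_correct,
            "auc": cv.auc,
        }
        f = cv.folds.copy()
        f.insert(0, "measure", m)
        fold_frames.append(f)
    pd.concat(fold_frames).to_csv(out / "discrimination_folds.csv", index=False)
    _dump_json(discrimination, out / "discrimination_metrics.json")

    # --- prognosis ----------------------------------------------------------
    prognosis = {}
    for name, feats in (("bg", BG_FEATURES), ("bg+symptoms", COMBINED_FEATURES)):
        X, y = derived_features(frame, feats)
        report = loocv_tree(X, y, seed=seed)
        prognosis[name] = {
            "selected_cp": report.selected_cp,
            "overall_accuracy": report.overall_accuracy,
            "accuracy_ci": list(report.accuracy_ci),
            "per_class": report.per_class.to_dict(orient="records"),
            "tree": report.tree.root.to_dict(report.tree.class_names),
        }
        report.per_class.to_csv(out / f"tree_metrics_{name.replace('+', '_')}.csv", index=False)
        report.fold_predictions.to_csv(
            out / f"tree_folds_{name.replace('+', '_')}.csv", index=False
        )
    _dump_json(prognosis, out / "tree_reports.json")

    # --- repeated reference comparisons ------------------------------------
    comp_rows, comp_summary = [], {}
    for m in ("TOJ", "TOJc", "DUR"):
        col = m.lower()
        for timepoint, values in (
            ("initial", frame[col].to_numpy()),
            ("discharge", paired[f"discharge_{col}"].to_numpy()),
        ):
            exp = repeated_reference_comparison(
                values,
                measure_params[m],
                reps=config.reps,
                alpha=config.alpha,
                seed=seed,
                measure=m,
                timepoint=timepoint,
            )
            comp_summary[f"{m}_{timepoint}"] = exp.pct_significant
            for rep, p in enumerate(exp.p_values):
                comp_rows.append(
                    {"measure": m, "timepoint": timepoint, "rep": rep, "p": p}
                )
    pd.DataFrame(comp_rows).to_csv(out / "comparison_pvalues.csv", index=False)
    _dump_json(comp_summary, out / "comparison_summary.json")

    # --- paired within-subject change ---------------------------------------
    wilcoxon = {}
    for m in ("TOJ", "TOJc", "DUR", "PST", "SSS"):
        col = m.lower()
        w, p = wilcoxon_signed_rank(
            paired[col].to_numpy(), paired[f"discharge_{col}"].to_numpy()
        )
        wilcoxon[m] = {"W": w, "p": p}
    _dump_json(wilcoxon, out / "wilcoxon_paired.json")

    manifest = {
        "seed": seed,
        "version": __version__,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_records": len(records),
        "n_paired": int(len(paired)),
    }
    _dump_json(manifest, out / "manifest.json")

    return {
        "pooled_reference": pooled_df,
        "cohort": frame,
        "discrimination": discrimination,
        "prognosis": prognosis,
        "comparisons": comp_summary,
        "wilcoxon": wilcoxon,
        "manifest": manifest,
    }
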