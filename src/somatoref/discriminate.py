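"""Diagnostic discrimination: LOOCV logistic regression against a
simulated healthy reference.

For each somatosensory measure, one healthy reference sample of the same
size as the patient sample is simulated (once, then frozen for the run),
the two samples are labelled, and a univariable logistic regression is
evaluated by leave-one-out cross-validation: each of the 2n cases is
held out in turn, the model refit on the remaining 2n-1, and the
left-out case classified at probability threshold 0.5.  Sensitivity,
specificity, predictive values, percent correctly classified and the
rank-based AUC of the left-out probabilities summarise discriminative
utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .simulate import GammaParams, draw_reference_sample

__all__ = [
    "SeparationError",
    "CVMetrics",
    "fit_logistic",
    "predict_proba",
    "roc_auc",
    "confusion_metrics",
    "loocv_discriminate",
]

logger = logging.getLogger(__name__)

#: Ridge penalty applied to the slope when a LOOCV training fold is
#: completely separated (the unpenalised MLE diverges there but the fold
#: must still emit a prediction).
SEPARATION_RIDGE = 1e-4


class SeparationError(RuntimeError):
    """Unpenalised logistic MLE does not exist (complete separation)."""


@dataclass
class CVMetrics:
    """Leave-one-out discrimination metrics for one measure.

    Fractions in [0, 1] except ``pct_correct`` (percentage).  ``folds``
    holds one row per case: id, true class, left-out predicted
    probability and predicted class.
    """

    measure: str
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    pct_correct: float
    auc: float
    folds: pd.DataFrame
    seed: int


def _check_binary(values, labels):
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return x, y


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    # For a univariable model, complete separation <=> the classes are
    # divided by a threshold on x.
    return max(x[y == 1]) < min(x[y == 0]) or max(x[y == 0]) < min(x[y == 1])


def fit_logistic(
    values,
    labels,
    ridge: float = 0.0,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Maximum-likelihood fit of P(y=1|x) = logistic(a + b*x).

    Newton-Raphson (IRLS) iterated until the log-likelihood change falls
    below ``tol``.  ``ridge`` adds an L2 penalty (ridge/2)*b^2 on the
    slope only; with ridge = 0, complete separation raises
    :class:`SeparationError` because the MLE diverges.
    Returns (intercept, slope).
    """
    x, y = _check_binary(values, labels)
    if ridge == 0.0 and _is_separated(x, y):
        raise SeparationError("classes are completely separated on this predictor")
    design = np.column_stack([np.ones_like(x), x])
    penalty = np.diag([0.0, ridge])
    beta = np.zeros(2)
    last_ll = -np.inf
    for _ in range(max_iter):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta))) - 0.5 * ridge * beta[1] ** 2
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = design.T @ (y - p) - penalty @ beta
        hess = design.T @ (design * w[:, None]) + penalty
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular Hessian during fit: {exc}") from exc
        beta = beta + step
        if abs(ll - last_ll) < tol:
            break
        last_ll = ll
    else:
        raise SeparationError("logistic fit did not converge")
    return float(beta[0]), float(beta[1])


def predict_proba(intercept: float, slope: float, values) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(intercept + slope * np.asarray(values, dtype=float))))


def roc_auc(scores, labels) -> float:
    """Rank-based AUC with ties counted one half.

    Equivalent to trapezoidal integration of the empirical ROC curve and
    to U/(n1*n0) from the Mann-Whitney statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    return float((np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def confusion_metrics(predicted, truth) -> dict:
    """Standard 2x2 metrics; zero-denominator ratios are None, not 0.

    ``pct_correct`` is a percentage of all cases.
    """
    pred = np.asarray(predicted, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "pct_correct": 100.0 * (tp + tn) / len(true),
    }


def loocv_discriminate(
    patient_values,
    params: GammaParams,
    seed: int = 0,
    threshold: float = 0.5,
    measure: str = "",
) -> CVMetrics:
    """LOOCV logistic discrimination of patients vs a simulated reference.

    One reference sample of equal size is drawn once and frozen (the only
    randomness); label 1 = patient, 0 = healthy reference.  Folds with
    complete separation are refit with a small ridge penalty
    (:data:`SEPARATION_RIDGE`) so every fold emits a prediction.
    """
    patient = np.asarray(patient_values, dtype=float)
    if patient.size == 0:
        raise ValueError("patient sample is empty")
    rng = substream(seed, "discrimination", measure)
    reference = draw_reference_sample(params, len(patient), rng)
    x = np.concatenate([patient, reference])
    y = np.concatenate([np.ones(len(patient)), np.zeros(len(reference))])
    ids = [f"mtbi{i+1}" for i in range(len(patient))] + [
        f"ref{i+1}" for i in range(len(reference))
    ]
    probs = np.empty(len(x))
    for i in range(len(x)):
        mask = np.ones(len(x), dtype=bool)
        mask[i] = False
        try:
            a, b = fit_logistic(x[mask], y[mask])
        except SeparationError:
            logger.warning(
                "%s: complete separation in fold %d; refitting with ridge %.1e",
                measure or "discrimination",
                i,
                SEPARATION_RIDGE,
            )
            a, b = fit_logistic(x[mask], y[mask], ridge=SEPARATION_RIDGE)
        probs[i] = predict_proba(a, b, x[i : i + 1])[0]
    preds = (probs >= threshold).astype(int)
    metrics = confusion_metrics(preds, y.astype(int))
    folds = pd.DataFrame(
        {"case_id": ids, "true_class": y.astype(int), "probability": probs, "predicted_class": preds}
    )
    return CVMetrics(
        measure=measure,
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        ppv=metrics["ppv"],
        npv=metrics["npv"],
        pct_correct=metrics["pct_correct"],
        auc=roc_auc(probs, y),
        folds=folds,
        seed=seed,
    )
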