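"""Metric-threshold vs reader-consensus agreement (Cohen's kappa).

Given per-slice metric values and the readers' consensus accept/reject
labels, a candidate acceptance threshold turns the metric into a second
binary rater; Cohen's kappa measures chance-corrected agreement between
that rater and the readers.  Sweeping the threshold over all observed
metric values traces an agreement curve whose argmax is the
kappa-maximizing threshold.  The "no-rejection" threshold is the extreme
metric value among rejected slices: every slice strictly beyond it (in
the better direction) was accepted by the readers.

Conventions: thresholds are boundary-inclusive (higher-is-better metrics
accept value >= t; lower-is-better accept value <= t); the candidate grid
is the sorted unique observed values plus one sentinel beyond each end;
kappa is undefined (nan) where chance agreement p_e = 1, and undefined
values are excluded from the argmax; argmax ties break toward the
stricter threshold (larger for higher-is-better, smaller otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "HIGHER_IS_BETTER",
    "AgreementCurve",
    "NoRejectSummary",
    "cohen_kappa",
    "classify_by_threshold",
    "sweep",
    "no_rejection_threshold",
    "KappaThresholdClassifier",
]

#: Orientation of each metric: does a larger value mean a better contour?
HIGHER_IS_BETTER = {
    "dice": True,
    "hd95": False,
    "precision": True,
    "sensitivity": True,
    "pixel_accuracy": True,
}

_DIRECTIONS = ("higher_is_better", "lower_is_better")


def _higher_better(direction) -> bool:
    if isinstance(direction, bool):
        return direction
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    return direction == "higher_is_better"


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa between two binary label vectors.

    kappa = (p_o - p_e) / (1 - p_e), with p_e the sum of the products of
    the two raters' marginal proportions.  Returns ``nan`` when p_e = 1
    (both raters constant with equal marginals — agreement has no chance
    correction).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must be 1D of equal length, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty label vectors")
    n = a.size
    classes = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for c in classes:
        p_e += float(np.mean(a == c)) * float(np.mean(b == c))
    if p_e >= 1.0 - 1e-15:
        return np.nan
    return (p_o - p_e) / (1.0 - p_e)


def classify_by_threshold(values, t: float, direction="higher_is_better") -> np.ndarray:
    """Boolean accept labels from an inclusive threshold on metric values.

    higher_is_better: accept iff value >= t; lower_is_better: accept iff
    value <= t.
    """
    v = np.asarray(values, dtype=float)
    return v >= t if _higher_better(direction) else v <= t


@dataclass
class AgreementCurve:
    """Kappa as a function of candidate acceptance thresholds for one metric."""

    metric_name: str
    direction: str
    thresholds: np.ndarray
    kappas: np.ndarray
    best_threshold: float
    best_kappa: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "direction": self.direction,
            "thresholds": [float(t) for t in self.thresholds],
            "kappas": [None if np.isnan(k) else float(k) for k in self.kappas],
            "best_threshold": None if np.isnan(self.best_threshold) else float(self.best_threshold),
            "best_kappa": None if np.isnan(self.best_kappa) else float(self.best_kappa),
            "degenerate": bool(self.degenerate),
        }


@dataclass
class NoRejectSummary:
    """The metric value beyond which no slice was rejected by the readers."""

    metric_name: str
    direction: str
    boundary_value: float
    n_beyond: int
    no_rejected_slices: bool = False

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "direction": self.direction,
            "boundary_value": float(self.boundary_value),
            "n_beyond": int(self.n_beyond),
            "no_rejected_slices": bool(self.no_rejected_slices),
        }


def _check_values_labels(values, accepted):
    v = np.asarray(values, dtype=float)
    y = np.asarray(accepted, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError(f"values/labels must be 1D of equal length, got {v.shape} vs {y.shape}")
    if np.isnan(v).any():
        raise ValueError(
            "undefined (nan) metric values must be excluded (with a tally) before sweeping"
        )
    return v, y


def sweep(values, accepted, direction="higher_is_better", metric_name: str = "") -> AgreementCurve:
    """Agreement curve over all observed thresholds, with its argmax.

    Candidate thresholds are the sorted unique observed values plus one
    sentinel beyond each end (so the all-accept and all-reject regimes
    appear on the curve).  When the consensus is single-class, every
    kappa is undefined or 0 and the curve is flagged degenerate.
    """
    v, y = _check_values_labels(values, accepted)
    if v.size < 2:
        raise ValueError("need at least 2 slices to sweep")
    higher = _higher_better(direction)
    dirname = "higher_is_better" if higher else "lower_is_better"
    uniq = np.unique(v)
    span = max(uniq[-1] - uniq[0], 1.0)
    cand = np.concatenate([[uniq[0] - 0.5 * span], uniq, [uniq[-1] + 0.5 * span]])
    kappas = np.array(
        [cohen_kappa(classify_by_threshold(v, t, higher), y) for t in cand]
    )
    defined = ~np.isnan(kappas)
    both_classes = 0 < y.sum() < y.size
    if not both_classes:
        return AgreementCurve(metric_name, dirname, cand, kappas, np.nan, np.nan, degenerate=True)
    best_kappa = float(np.nanmax(kappas)) if defined.any() else np.nan
    if np.isnan(best_kappa):
        return AgreementCurve(metric_name, dirname, cand, kappas, np.nan, np.nan, degenerate=True)
    attaining = cand[defined & (kappas == best_kappa)]
    # stricter threshold on ties: larger for higher-better, smaller otherwise
    best_t = float(attaining.max() if higher else attaining.min())
    return AgreementCurve(metric_name, dirname, cand, kappas, best_t, best_kappa)


def no_rejection_threshold(
    values, accepted, direction="higher_is_better", metric_name: str = ""
) -> NoRejectSummary:
    """Extreme metric value among rejected slices, and the count beyond it.

    boundary_value is the best metric value among *rejected* slices (max
    for higher-is-better, min for lower-is-better); n_beyond counts the
    accepted slices strictly beyond it.  With no rejected slices the
    boundary is the worst observed value, n_beyond = n, and the summary
    is flagged.
    """
    v, y = _check_values_labels(values, accepted)
    higher = _higher_better(direction)
    dirname = "higher_is_better" if higher else "lower_is_better"
    rejected = v[~y]
    if rejected.size == 0:
        worst = float(v.min() if higher else v.max())
        return NoRejectSummary(metric_name, dirname, worst, int(v.size), no_rejected_slices=True)
    boundary = float(rejected.max() if higher else rejected.min())
    beyond = (v > boundary) if higher else (v < boundary)
    return NoRejectSummary(metric_name, dirname, boundary, int(np.sum(beyond & y)))


class KappaThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Single-feature accept/reject classifier fitted by kappa maximization.

    Wraps :func:`sweep` in the scikit-learn estimator protocol: ``fit``
    selects the acceptance threshold maximizing Cohen's kappa against the
    provided consensus labels, ``predict`` applies the inclusive
    threshold rule.  Fitted attributes: ``threshold_``, ``kappa_``,
    ``curve_`` (the full :class:`AgreementCurve`).

    Parameters
    ----------
    direction : {"higher_is_better", "lower_is_better"}
        Orientation of the metric (e.g. Dice is higher-is-better, HD95
        lower-is-better).
    metric_name : str
        Label recorded on the fitted curve.
    """

    def __init__(self, direction: str = "higher_is_better", metric_name: str = ""):
        self.direction = direction
        self.metric_name = metric_name

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single metric column")
            X = X[:, 0]
        y = np.asarray(y).astype(bool)
        self.curve_ = sweep(X, y, self.direction, self.metric_name)
        self.threshold_ = self.curve_.best_threshold
        self.kappa_ = self.curve_.best_kappa
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return classify_by_threshold(X, self.threshold_, self.direction)
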