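"""Two-class evaluation metrics: confusion counts, kappa, rates, F-score.

Conventions follow the BCI-classification literature: +1 is the positive
class, kappa corrects accuracy for the two-class chance level of 0.5, and
sensitivity / specificity / precision / F-score are reported in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvaluationReport",
    "UndefinedMetricError",
    "confusion",
    "f_score",
    "kappa",
    "rates",
]


class UndefinedMetricError(ValueError):
    """A rate's denominator is zero, so the metric is undefined (not 0)."""


def kappa(acc: float, rand: float = 0.5) -> float:
    """Chance-corrected accuracy (acc - rand) / (1 - rand).

    ``rand`` is the accuracy of random classification, 0.5 for a balanced
    two-class problem.  Both arguments are proportions in [0, 1].
    """
    if not 0.0 <= acc <= 1.0:
        raise ValueError("acc must be a proportion in [0, 1]")
    if not 0.0 <= rand < 1.0:
        raise ValueError("rand must lie in [0, 1); rand = 1 leaves kappa undefined")
    return (acc - rand) / (1.0 - rand)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (both in percent)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        raise UndefinedMetricError("F-score undefined: precision + recall is zero")
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvaluationReport:
    """2x2 confusion counts plus the derived metric suite.

    Accuracy and kappa are proportions; sensitivity, specificity, precision
    and F-score are percentages.  Rates with a zero denominator raise
    :class:`UndefinedMetricError` rather than silently returning 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    rand: float = 0.5

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer count")
            setattr(self, name, int(v))
        if self.n == 0:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def kappa(self) -> float:
        return kappa(self.accuracy, self.rand)

    @property
    def sensitivity(self) -> float:
        """Recall of the positive class, percent."""
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("sensitivity undefined: no positive samples")
        return 100.0 * self.tp / (self.tp + self.fn)

    recall = sensitivity

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("specificity undefined: no negative samples")
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            raise UndefinedMetricError("precision undefined: no positive predictions")
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def f_score(self) -> float:
        """Harmonic mean of precision and recall, percent."""
        p, r = self.precision, self.sensitivity
        if p + r == 0:
            raise UndefinedMetricError("F-score undefined: precision + recall is zero")
        return 2.0 * p * r / (p + r)

    def to_dict(self) -> dict:
        out = {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "n": self.n,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "rand": self.rand,
        }
        for name in ("sensitivity", "specificity", "precision", "f_score"):
            try:
                out[name] = getattr(self, name)
            except UndefinedMetricError:
                out[name] = None
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def tsv_row(self, n_selected: int | None = None) -> str:
        """One tab-separated row: SC/SF, ACC%, Kappa, F, SEN, SPE, PRE."""

        def fmt(name: str) -> str:
            try:
                return f"{getattr(self, name):.2f}"
            except UndefinedMetricError:
                return "NA"

        cells = [
            "" if n_selected is None else str(n_selected),
            f"{100.0 * self.accuracy:.2f}",
            f"{self.kappa:.2f}",
            fmt("f_score"),
            fmt("sensitivity"),
            fmt("specificity"),
            fmt("precision"),
        ]
        return "\t".join(cells)


def confusion(y_true, y_pred, positive_label: int = 1, rand: float = 0.5) -> EvaluationReport:
    """Confusion counts for +-1 label vectors, +1 the positive class by default."""
    t = np.asarray(y_true).ravel()
    p = np.asarray(y_pred).ravel()
    if t.shape != p.shape:
        raise ValueError("true and predicted label vectors must have equal length")
    if not (np.all(np.isin(t, (-1, 1))) and np.all(np.isin(p, (-1, 1)))):
        raise ValueError("labels must take values in {-1, +1}")
    pos = t == positive_label
    pred_pos = p == positive_label
    return EvaluationReport(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        rand=rand,
    )


def rates(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Sensitivity, specificity, precision and F-score (percent) from counts."""
    r = EvaluationReport(tp=tp, tn=tn, fp=fp, fn=fn)
    return {
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
        "precision": r.precision,
        "f_score": r.f_score,
    }
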