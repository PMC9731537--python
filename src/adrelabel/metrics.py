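"""Evaluation statistics: one-vs-all AUC, balanced accuracy, aggregation."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "one_vs_all_auc",
    "macro_auc",
    "balanced_accuracy",
    "aggregate_repeats",
]


class UndefinedMetricError(ValueError):
    """A metric has no defined value for the given labels (e.g. AUC with a
    single class)."""


def one_vs_all_auc(scores, labels, positive_class) -> float:
    """P(random positive outranks random negative); ties get half credit.

    Mann-Whitney formulation: AUC = (R_pos - n_pos (n_pos + 1)/2) /
    (n_pos n_neg) where R_pos is the positive rank sum under midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined: class {positive_class!r} needs both positives "
            "and negatives")
    ranks = stats.rankdata(scores)  # midranks handle ties at 1/2 credit
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def macro_auc(score_matrix, labels, classes) -> tuple[float, dict]:
    """Mean one-vs-all AUC over the classes present in ``labels``.

    ``score_matrix`` holds one score column per entry of ``classes``.
    Classes absent from the labels are excluded with a warning.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    labels = np.asarray(labels)
    per_class: dict = {}
    for j, c in enumerate(classes):
        try:
            per_class[c] = one_vs_all_auc(score_matrix[:, j], labels, c)
        except UndefinedMetricError:
            logger.warning("class %r absent; excluded from macro AUC", c)
    if not per_class:
        raise UndefinedMetricError("no class has a defined AUC")
    return float(np.mean(list(per_class.values()))), per_class


def balanced_accuracy(predictions, labels) -> float:
    """Unweighted mean of per-class recall over classes with true samples."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    recalls = []
    for c in np.unique(labels):
        mask = labels == c
        recalls.append(float((predictions[mask] == c).mean()))
    return float(np.mean(recalls))


@dataclass
class MetricsReport:
    """Evaluation results for one run or a collection of repeats."""

    per_class_auc: dict = field(default_factory=dict)
    macro_auc: float = np.nan
    balanced_accuracy: float = np.nan
    per_repeat: pd.DataFrame | None = None  # repeat, macro_auc, balanced_accuracy
    comparison: dict | None = None  # mean_difference, t_statistic, p_value

    def summary_row(self) -> dict:
        row = {"macro_auc": self.macro_auc,
               "balanced_accuracy": self.balanced_accuracy}
        row.update({f"auc_{c}": v for c, v in self.per_class_auc.items()})
        return row

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_class_auc": self.per_class_auc,
            "macro_auc": self.macro_auc,
            "balanced_accuracy": self.balanced_accuracy,
        }
        if self.per_repeat is not None:
            payload["per_repeat"] = self.per_repeat.to_dict(orient="records")
        if self.comparison is not None:
            payload["comparison"] = self.comparison
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def to_tsv_row(self, path: str | Path) -> None:
        pd.DataFrame([self.summary_row()]).to_csv(path, sep="\t", index=False)


def aggregate_repeats(repeats: list[MetricsReport],
                      paired: list[MetricsReport] | None = None) -> MetricsReport:
    """Mean +/- SD across repeats; optional paired comparison via a
    two-sided t-test on the macro AUC series."""
    if not repeats:
        raise ValueError("at least one repeat required")
    frame = pd.DataFrame(
        {"repeat": range(len(repeats)),
         "macro_auc": [r.macro_auc for r in repeats],
         "balanced_accuracy": [r.balanced_accuracy for r in repeats]}
    )
    report = MetricsReport(
        per_class_auc=_mean_dicts([r.per_class_auc for r in repeats]),
        macro_auc=float(frame["macro_auc"].mean()),
        balanced_accuracy=float(frame["balanced_accuracy"].mean()),
        per_repeat=frame,
    )
    report.macro_auc_sd = float(frame["macro_auc"].std(ddof=1)) if len(frame) > 1 else np.nan
    report.balanced_accuracy_sd = (
        float(frame["balanced_accuracy"].std(ddof=1)) if len(frame) > 1 else np.nan)
    if paired is not None:
        if len(paired) != len(repeats):
            raise ValueError("paired series must have the same length")
        a = np.array([r.macro_auc for r in repeats])
        b = np.array([r.macro_auc for r in paired])
        comparison = {"mean_difference": float((a - b).mean())}
        if len(a) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            comparison.update({"t_statistic": float(t), "p_value": float(p)})
        report.comparison = comparison
    return report


def _mean_dicts(dicts: list[dict]) -> dict:
    keys = sorted({k for d in dicts for k in d})
    return {k: float(np.mean([d[k] for d in dicts if k in d])) for k in keys}
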