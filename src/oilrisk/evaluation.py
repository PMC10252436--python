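"""Forecast and risk-level scoring.

Regression quality is reported as RMSE and MAE per model and indicator.
Risk-level quality is reported as one-vs-rest precision, recall and F1 per
level plus their macro (unweighted) means, from a confusion matrix over
the ordered levels.  For level L: P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R).  A level absent from both truth and prediction has no
defined scores and is excluded from the macro mean (with a logged notice).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: internal model keys -> display names used in reports
MODEL_DISPLAY = {"lstm": "LSTM", "xgb": "XGBoost", "combined": "LSTM-XGBoost"}


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y_true, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if a.size == 0:
        raise ValidationError("empty evaluation input")
    return a, b


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error."""
    a, b = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mae(y_true, y_pred) -> float:
    """Mean absolute error."""
    a, b = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(a - b)))


def level_scores(true_levels, pred_levels, labels) -> dict:
    """Per-level and macro precision/recall/F1 over an ordered level set.

    Returns a dict with keys "per_level" (level -> {tp, fp, fn, precision,
    recall, f1}), "macro" ({precision, recall, f1}), "confusion" (row =
    true level, column = predicted level, in ``labels`` order) and
    "excluded" (levels absent from both truth and prediction).
    """
    t = np.asarray(true_levels)
    p = np.asarray(pred_levels)
    if t.shape != p.shape or t.size == 0:
        raise ValidationError("level sequences must be equal-length and non-empty")
    labels = list(labels)
    unknown = (set(t) | set(p)) - set(labels)
    if unknown:
        raise ValidationError(f"unknown level label(s): {sorted(unknown)}")

    cm = confusion_matrix(t, p, labels=labels)
    per_level: dict[str, dict] = {}
    excluded: list[str] = []
    macro_p, macro_r, macro_f = [], [], []
    for i, lv in enumerate(labels):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum() - tp)
        fn = int(cm[i, :].sum() - tp)
        if tp + fp + fn == 0:
            excluded.append(lv)
            logger.info("level '%s' absent from truth and prediction; excluded", lv)
            continue
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_level[lv] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": prec, "recall": rec, "f1": f1,
        }
        macro_p.append(prec)
        macro_r.append(rec)
        macro_f.append(f1)
    return {
        "per_level": per_level,
        "macro": {
            "precision": float(np.mean(macro_p)),
            "recall": float(np.mean(macro_r)),
            "f1": float(np.mean(macro_f)),
        },
        "confusion": cm.tolist(),
        "labels": labels,
        "excluded": excluded,
    }


@dataclass
class EvaluationReport:
    """Regression errors per (model, indicator) and level scores per model."""

    regression: dict = field(default_factory=dict)  # model -> indicator -> {rmse, mae}
    classification: dict = field(default_factory=dict)  # model -> level_scores dict
    n: int = 0
    averaging: str = "macro"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "averaging": self.averaging,
            "regression": self.regression,
            "classification": self.classification,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def to_markdown(self) -> str:
        """Risk-level scoreboard (rows: models; columns: P%, R%, F1%,
        two-decimal percent formatting) plus a regression-error table."""
        lines = ["# Risk level prediction", "", "| Model | P% | R% | F1% |",
                 "|---|---|---|---|"]
        for key, name in MODEL_DISPLAY.items():
            if key not in self.classification:
                continue
            m = self.classification[key]["macro"]
            lines.append(
                f"| {name} | {100 * m['precision']:.2f}% | "
                f"{100 * m['recall']:.2f}% | {100 * m['f1']:.2f}% |"
            )
        lines += ["", "# Forecast errors", "",
                  "| Model | Indicator | RMSE | MAE |", "|---|---|---|---|"]
        for key, name in MODEL_DISPLAY.items():
            for ind, errs in self.regression.get(key, {}).items():
                lines.append(
                    f"| {name} | {ind} | {errs['rmse']:.6g} | {errs['mae']:.6g} |"
                )
        return "\n".join(lines) + "\n"


def evaluate_pipeline(
    combined: pd.DataFrame, grader, truth_levels: pd.DataFrame | None = None
) -> EvaluationReport:
    """Score the two base models and the fused model on the test period.

    ``combined`` is the output of :func:`oilrisk.combiner.
    combine_predictions` (columns city, indicator, week, f1, f2, combined,
    y_true).  Predicted (ILCR, MOE, NIPI) triples are risk-graded with the
    fitted ``grader``; the reference levels come from grading the observed
    triples, unless ``truth_levels`` (city, week, level) is given — the
    planted-truth variant used in recovery tests.
    """
    for col in ("f1", "f2", "combined", "y_true"):
        if col not in combined.columns:
            raise ValidationError(f"missing column '{col}' in combined forecasts")

    def pivot(col: str) -> pd.DataFrame:
        wide = combined.pivot_table(
            index=["city", "week"], columns="indicator", values=col
        ).reset_index()
        return wide

    model_cols = {"lstm": "f1", "xgb": "f2", "combined": "combined"}
    truth_wide = pivot("y_true")
    if truth_levels is not None:
        merged = truth_wide.merge(truth_levels, on=["city", "week"], how="left")
        if merged["level"].isna().any():
            raise ValidationError("truth levels missing for some city-weeks")
        true_lv = merged["level"].to_numpy()
    else:
        true_lv = grader.predict(truth_wide)

    report = EvaluationReport(n=len(truth_wide))
    for model, col in model_cols.items():
        wide = pivot(col)
        pred_lv = grader.predict(wide)
        report.classification[model] = level_scores(
            true_lv, pred_lv, labels=list(grader.level_names_)
        )
        report.regression[model] = {}
        for ind, grp in combined.groupby("indicator"):
            report.regression[model][ind] = {
                "rmse": rmse(grp["y_true"], grp[col]),
                "mae": mae(grp["y_true"], grp[col]),
            }
    return report
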