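"""Inverse-error fusion of two forecast series.

The combined forecast is the pointwise convex combination
``f_t = w1·f1_t + w2·f2_t`` with weights inversely proportional to each
model's error: ``w1 = e2/(e1+e2)`` and ``w2 = e1/(e1+e2)``, so the model
with the smaller error carries the larger weight.  In static mode the
error of each model is its root-mean-square residual over the validation
window, computed once; in variable-weight (rolling) mode the errors are
recomputed at every forecast origin over the most recent ``window``
residuals, folding in test-period residuals as the true values become
known.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


def inverse_error_weights(eps1: float, eps2: float) -> tuple[float, float]:
    """Convex weights from two error magnitudes; the smaller error wins the
    larger weight.  Both errors zero → (0.5, 0.5)."""
    if eps1 < 0 or eps2 < 0:
        raise ValidationError("error magnitudes must be >= 0")
    total = eps1 + eps2
    if total == 0:
        return 0.5, 0.5
    w1 = eps2 / total
    return w1, 1.0 - w1


def combine(f1, f2, weights) -> np.ndarray:
    """Pointwise convex combination of two forecast series.

    ``weights`` is either one (w1, w2) pair applied throughout or an
    (n, 2) schedule with one pair per time point.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ValidationError("forecast series must have equal length")
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = np.broadcast_to(w, (len(f1), 2))
    if w.shape != (len(f1), 2):
        raise ValidationError("need one (w1, w2) pair per time point")
    return w[:, 0] * f1 + w[:, 1] * f2


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def rolling_weights(
    residuals1, residuals2, window: int = 7, n_steps: int | None = None
) -> np.ndarray:
    """Weight schedule over ``n_steps`` forecast origins.

    ``residuals1``/``residuals2`` are each model's full residual history in
    chronological order: validation residuals first, then any test-period
    residuals that become available as forecasting proceeds.  At origin t
    the error of model i is the root-mean-square of its last ``window``
    residuals available *before* t (the trailing ``n_steps − t`` entries
    are still in the future and excluded).  ``window = 0`` selects static
    mode: the full pre-test history is used once and reused at every
    origin.  With no residuals available at an origin the weights fall
    back to (0.5, 0.5).
    """
    r1 = np.asarray(residuals1, dtype=float)
    r2 = np.asarray(residuals2, dtype=float)
    if r1.shape != r2.shape:
        raise ValidationError("residual histories must have equal length")
    if window < 0:
        raise ValidationError("window must be >= 0 (0 = static)")
    if n_steps is None:
        n_steps = 1
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    if len(r1) < n_steps:
        raise ValidationError("residual history shorter than the forecast span")

    # The trailing n_steps entries of the history are the test-period
    # residuals for origins 0..n_steps-1; the residual of origin t is only
    # realized *after* t, so origin t sees the first (len - n_steps + t).
    base = len(r1) - n_steps
    schedule = np.empty((n_steps, 2))
    for t in range(n_steps):
        avail = base if window == 0 else base + t
        hist1, hist2 = r1[:avail], r2[:avail]
        if window > 0:
            hist1, hist2 = hist1[-window:], hist2[-window:]
        if len(hist1) == 0:
            logger.warning("no residual history at origin %d; equal weights", t)
            schedule[t] = (0.5, 0.5)
        else:
            schedule[t] = inverse_error_weights(_rms(hist1), _rms(hist2))
    return schedule


def combine_predictions(
    predictions: pd.DataFrame, mode: str = "rolling", window: int = 7
) -> pd.DataFrame:
    """Fuse the two base models' forecasts per (city, indicator) series.

    ``predictions`` is the long frame from
    :func:`oilrisk.forecasting.forecast_all` (columns city, indicator,
    week, model, split, y_true, y_pred).  Weights are computed per series
    from that series' own residuals: the in-sample ("train") residuals
    seed the history, and in rolling mode each test residual is folded in
    once its week has passed.

    Returns a frame with columns city, indicator, week, f1 (recurrent
    model), f2 (tree model), omega1, omega2, combined, y_true.
    """
    if mode not in ("static", "rolling"):
        raise ValidationError(f"unknown combination mode '{mode}'")
    if mode == "rolling" and window < 1:
        raise ValidationError("rolling mode needs window >= 1")

    out_rows = []
    for (city, ind), grp in predictions.groupby(["city", "indicator"], sort=True):
        piv = {
            (model, split): g.sort_values("week")
            for (model, split), g in grp.groupby(["model", "split"])
        }
        try:
            lstm_tr, xgb_tr = piv[("lstm", "train")], piv[("xgb", "train")]
            lstm_te, xgb_te = piv[("lstm", "test")], piv[("xgb", "test")]
        except KeyError as exc:
            raise ValidationError(f"missing model/split rows for {city}/{ind}") from exc

        val_res1 = lstm_tr["y_pred"].to_numpy() - lstm_tr["y_true"].to_numpy()
        val_res2 = xgb_tr["y_pred"].to_numpy() - xgb_tr["y_true"].to_numpy()
        f1 = lstm_te["y_pred"].to_numpy()
        f2 = xgb_te["y_pred"].to_numpy()
        y = lstm_te["y_true"].to_numpy()
        n = len(f1)

        hist1 = np.concatenate([val_res1, f1 - y])
        hist2 = np.concatenate([val_res2, f2 - y])
        w = rolling_weights(
            hist1, hist2, window=0 if mode == "static" else window, n_steps=n
        )
        fused = combine(f1, f2, w)
        weeks = lstm_te["week"].to_numpy()
        for j in range(n):
            out_rows.append(
                {
                    "city": city,
                    "indicator": ind,
                    "week": int(weeks[j]),
                    "f1": f1[j],
                    "f2": f2[j],
                    "omega1": w[j, 0],
                    "omega2": w[j, 1],
                    "combined": fused[j],
                    "y_true": y[j],
                }
            )
    return pd.DataFrame(out_rows)
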