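"""One-step-ahead forecasting of weekly risk indicators.

Each (city, indicator) series is turned into supervised lag windows — the
seven preceding weekly values predict the next week — and split
chronologically 6:4 into train and test.  Two heterogeneous base models
are fitted per series: a stacked recurrent network (:class:`~oilrisk.nn.
LSTMRegressor`) and gradient-boosted trees (XGBoost, squared-error
objective) on the same lag features.  An optional exhaustive grid search
with blocked ten-fold cross-validation tunes the tree hyperparameters per
series.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from xgboost import XGBRegressor

from .exceptions import ValidationError
from .nn import LSTMRegressor

INDICATOR_COLUMNS = ("ilcr", "moe", "nipi")


@dataclass
class LstmConfig:
    units: tuple[int, ...] = (64, 32)
    dropout: float = 0.2
    activation: str = "sigmoid"
    loss: str = "mae"
    learning_rate: float = 0.05
    clipnorm: float = 1.0
    epochs: int = 150
    batch_size: int = 8


@dataclass
class XgbConfig:
    """Fixed tree hyperparameters (used when tuning is off)."""

    learning_rate: float = 0.1
    gamma: float = 0.0
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    max_depth: int = 3
    n_estimators: int = 200


#: Default exhaustive-search grid; ranges follow the usual guidance
#: (learning rate 0.01–0.2, subsample 0.5–1, depth 3–10).
DEFAULT_XGB_GRID: dict[str, list] = {
    "learning_rate": [0.05, 0.1, 0.2],
    "gamma": [0.0, 0.1],
    "subsample": [0.8, 1.0],
    "colsample_bytree": [0.8, 1.0],
    "max_depth": [3, 6],
}


@dataclass
class ForecastConfig:
    timesteps: int = 7
    split_ratio: float = 0.6
    lstm: LstmConfig = field(default_factory=LstmConfig)
    xgb: XgbConfig = field(default_factory=XgbConfig)
    xgb_grid: dict = field(default_factory=lambda: dict(DEFAULT_XGB_GRID))
    cv_folds: int = 10

    def validate(self) -> None:
        if self.timesteps < 1:
            raise ValidationError("timesteps must be >= 1")
        if not (0 < self.split_ratio < 1):
            raise ValidationError("split_ratio must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")


@dataclass
class Windows:
    """Supervised lag windows for one series, split chronologically."""

    X_train: np.ndarray
    y_train: np.ndarray
    t_train: np.ndarray  # chronological label of each training target
    X_test: np.ndarray
    y_test: np.ndarray
    t_test: np.ndarray


def make_windows(
    series, timesteps: int = 7, split_ratio: float = 0.6
) -> Windows:
    """Sliding lag windows of length ``timesteps`` predicting the next value.

    ``series`` may be a pandas Series indexed by week number (gaps are
    forward-filled, and any leading gap back-filled, before windowing) or a
    plain array.  The split is chronological at floor(split_ratio * len):
    windows whose target falls before the cut are training, the rest test.
    """
    if isinstance(series, pd.Series):
        idx = series.index.to_numpy()
        full = pd.RangeIndex(int(idx.min()), int(idx.max()) + 1)
        series = series.reindex(full).ffill().bfill()
        values = series.to_numpy(dtype=float)
        labels = series.index.to_numpy()
    else:
        values = np.asarray(series, dtype=float)
        labels = np.arange(len(values))

    n = len(values)
    min_len = timesteps + 3
    if n < min_len:
        raise ValidationError(
            f"series too short for windowing: need >= {min_len} values, got {n}"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite values in series")

    X = np.lib.stride_tricks.sliding_window_view(values[:-1], timesteps)
    y = values[timesteps:]
    t = labels[timesteps:]
    cut = int(np.floor(split_ratio * n))
    train = np.arange(len(y)) + timesteps < cut
    if not train.any() or train.all():
        raise ValidationError(
            "chronological split leaves an empty train or test partition"
        )
    return Windows(
        X_train=X[train].copy(),
        y_train=y[train].copy(),
        t_train=t[train].copy(),
        X_test=X[~train].copy(),
        y_test=y[~train].copy(),
        t_test=t[~train].copy(),
    )


def fit_lstm(windows: Windows, cfg: LstmConfig = LstmConfig(), seed: int = 0) -> LSTMRegressor:
    """Fit the recurrent base model on the training windows."""
    if len(windows.X_train) == 0:
        raise ValidationError("empty training window set")
    model = LSTMRegressor(
        units=cfg.units,
        dropout=cfg.dropout,
        activation=cfg.activation,
        loss=cfg.loss,
        learning_rate=cfg.learning_rate,
        clipnorm=cfg.clipnorm,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        seed=seed,
    )
    return model.fit(windows.X_train, windows.y_train)


def _xgb(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        objective="reg:squarederror",
        random_state=int(seed),
        n_jobs=1,
        verbosity=0,
        **params,
    )


def fit_xgb(windows: Windows, cfg: XgbConfig = XgbConfig(), seed: int = 0) -> XGBRegressor:
    """Fit the gradient-boosted tree base model on the lag features."""
    if len(windows.X_train) == 0:
        raise ValidationError("empty training window set")
    if not np.all(np.isfinite(windows.X_train)):
        raise ValidationError("non-finite values in training data")
    model = _xgb(vars(cfg).copy(), seed)
    model.fit(windows.X_train, windows.y_train)
    return model


def tune(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict[str, list],
    cv_folds: int = 10,
    seed: int = 0,
    model_factory: Callable[[dict, int], object] | None = None,
) -> tuple[dict, list[dict]]:
    """Exhaustive grid search scored by mean validation RMSE over blocked
    cross-validation folds.

    The training windows are cut into ``cv_folds`` contiguous blocks of
    near-equal size (they differ by at most one); each block serves once as
    the validation segment.  Returns the best hyperparameter combination
    and the full result table (one dict per combination with its fold
    scores and mean).
    """
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    n = len(y)
    if n < cv_folds:
        raise ValidationError(f"need >= {cv_folds} windows for {cv_folds}-fold CV")
    factory = model_factory or _xgb
    folds = np.array_split(np.arange(n), cv_folds)

    keys = sorted(grid)
    results = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        scores = []
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            model = factory(params, seed)
            model.fit(X[mask], y[mask])
            pred = model.predict(X[fold])
            scores.append(float(np.sqrt(np.mean((pred - y[fold]) ** 2))))
        results.append(
            {"params": params, "fold_rmse": scores, "mean_rmse": float(np.mean(scores))}
        )
    best = min(results, key=lambda r: r["mean_rmse"])
    return best["params"], results


def _series_seed(seed: int, city: str, indicator: str) -> int:
    return (zlib.crc32(f"{city}|{indicator}".encode()) ^ (seed & 0x7FFFFFFF)) % (2**31 - 1)


def forecast_all(
    triples: pd.DataFrame,
    cfg: ForecastConfig = ForecastConfig(),
    seed: int = 0,
    tune_xgb: bool = False,
) -> pd.DataFrame:
    """Fit both base models on every (city, indicator) series.

    Returns a long DataFrame with columns city, indicator, week, model
    ("lstm" or "xgb"), split ("train" for in-sample predictions, "test"
    for out-of-sample), y_true, y_pred.  In-sample rows provide the
    residual history the inverse-error combiner starts from.
    """
    cfg.validate()
    rows = []
    for city, group in triples.groupby("city", sort=True):
        group = group.sort_values("week")
        for ind in INDICATOR_COLUMNS:
            series = pd.Series(
                group[ind].to_numpy(float), index=group["week"].to_numpy(int)
            )
            win = make_windows(series, cfg.timesteps, cfg.split_ratio)
            s = _series_seed(seed, str(city), ind)

            lstm = fit_lstm(win, cfg.lstm, seed=s)
            if tune_xgb:
                params, _ = tune(
                    win.X_train, win.y_train, cfg.xgb_grid, cfg.cv_folds, seed=s
                )
                params.setdefault("n_estimators", cfg.xgb.n_estimators)
                xgb = _xgb(params, s).fit(win.X_train, win.y_train)
            else:
                xgb = fit_xgb(win, cfg.xgb, seed=s)

            for model_name, model in (("lstm", lstm), ("xgb", xgb)):
                for split, Xp, yp, tp in (
                    ("train", win.X_train, win.y_train, win.t_train),
                    ("test", win.X_test, win.y_test, win.t_test),
                ):
                    pred = model.predict(Xp)
                    for week, yt, yh in zip(tp, yp, pred):
                        rows.append(
                            {
                                "city": city,
                                "indicator": ind,
                                "week": int(week),
                                "model": model_name,
                                "split": split,
                                "y_true": float(yt),
                                "y_pred": float(yh),
                            }
                        )
    return pd.DataFrame(rows)
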