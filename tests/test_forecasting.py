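"""Window construction, chronological split, tree model and tuning."""

import numpy as np
import pandas as pd
import pytest

from oilrisk import ForecastConfig, forecast_all, make_windows, tune
from oilrisk.exceptions import ValidationError
from oilrisk.forecasting import LstmConfig, XgbConfig, fit_xgb


def test_window_enumeration():
    win = make_windows(np.arange(1.0, 11.0), timesteps=7, split_ratio=0.8)
    X = np.vstack([win.X_train, win.X_test])
    y = np.concatenate([win.y_train, win.y_test])
    assert len(y) == 3  # len - timesteps
    np.testing.assert_array_equal(X[0], np.arange(1.0, 8.0))
    assert y[0] == 8.0
    np.testing.assert_array_equal(y, [8.0, 9.0, 10.0])


def test_constant_series_constant_targets():
    win = make_windows(np.full(20, 3.5), timesteps=7, split_ratio=0.6)
    assert np.all(win.y_train == 3.5) and np.all(win.y_test == 3.5)


def test_window_count_identity(rng):
    for n in (14, 30, 53):
        s = rng.random(n)
        win = make_windows(s, timesteps=7, split_ratio=0.6)
        assert len(win.y_train) + len(win.y_test) == n - 7


def test_too_short_series_names_minimum():
    with pytest.raises(ValidationError) as exc:
        make_windows(np.arange(5.0), timesteps=7)
    assert "10" in str(exc.value)  # timesteps + 3


def test_chronological_split_no_leakage(rng):
    s = rng.random(53)
    win = make_windows(s, 7, 0.6)
    assert win.t_train.max() < win.t_test.min()
    # every lag vector is the 7 values immediately preceding its target
    for X, y, t in ((win.X_train, win.y_train, win.t_train),):
        for i in range(len(y)):
            np.testing.assert_array_equal(X[i], s[t[i] - 7 : t[i]])


def test_gaps_forward_filled():
    weeks = [w for w in range(1, 19) if w != 11]  # week 11 missing
    s = pd.Series(np.arange(1.0, 18.0), index=weeks)
    win = make_windows(s, timesteps=7, split_ratio=0.6)
    X = np.vstack([win.X_train, win.X_test])
    y = np.concatenate([win.y_train, win.y_test])
    full = np.concatenate([X[0], y])  # reconstructed filled series
    assert list(full[9:12]) == [10.0, 10.0, 11.0]  # week 11 repeats week 10


def test_xgb_fits_linear_series_nearly_exactly():
    s = np.arange(60, dtype=float)
    win = make_windows(s, 7, 0.9)
    model = fit_xgb(win, XgbConfig(max_depth=6, n_estimators=400), seed=0)
    pred = model.predict(win.X_train)
    rmse = np.sqrt(np.mean((pred - win.y_train) ** 2))
    assert rmse < 0.05 * s.std()


def test_xgb_deterministic(rng):
    s = rng.random(40)
    win = make_windows(s, 7, 0.6)
    cfg = XgbConfig(subsample=1.0, colsample_bytree=1.0)
    a = fit_xgb(win, cfg, seed=5).predict(win.X_test)
    b = fit_xgb(win, cfg, seed=5).predict(win.X_test)
    np.testing.assert_array_equal(a, b)
    assert len(a) == len(win.y_test)


def test_tune_singleton_grid(rng):
    s = rng.random(40)
    win = make_windows(s, 7, 0.9)
    grid = {"max_depth": [4], "learning_rate": [0.1]}
    best, results = tune(win.X_train, win.y_train, grid, cv_folds=5, seed=0)
    assert best == {"max_depth": 4, "learning_rate": 0.1}
    assert len(results) == 1


def test_tune_selects_minimum_score(rng):
    s = np.sin(np.arange(60) / 3) + 0.05 * rng.standard_normal(60)
    win = make_windows(s, 7, 0.9)
    grid = {"max_depth": [2, 4], "learning_rate": [0.05, 0.2]}
    best, results = tune(win.X_train, win.y_train, grid, cv_folds=5, seed=0)
    best_score = min(r["mean_rmse"] for r in results)
    chosen = next(r for r in results if r["params"] == best)
    assert chosen["mean_rmse"] == best_score
    assert all(chosen["mean_rmse"] <= r["mean_rmse"] for r in results)


def test_tune_fold_sizes_balanced(rng):
    n = 43
    folds = np.array_split(np.arange(n), 10)
    sizes = [len(f) for f in folds]
    assert max(sizes) - min(sizes) <= 1
    with pytest.raises(ValidationError):
        tune(rng.random((5, 7)), rng.random(5), {"max_depth": [3]}, cv_folds=10)


def test_tune_empty_grid_rejected(rng):
    with pytest.raises(ValidationError):
        tune(rng.random((20, 7)), rng.random(20), {}, cv_folds=5)


@pytest.fixture(scope="module")
def small_predictions(default_triples_module):
    cfg = ForecastConfig(lstm=LstmConfig(units=(8, 4), epochs=30))
    return forecast_all(default_triples_module, cfg, seed=1)


@pytest.fixture(scope="module")
def default_triples_module():
    from oilrisk import SyntheticConfig, generate
    from oilrisk.indices import compute_triples
    from oilrisk.preprocessing import substitute_nondetects, summarize

    sampling, consumption, _ = generate(
        SyntheticConfig(n_provinces=2, cities_per_province=2, seed=42)
    )
    return compute_triples(summarize(substitute_nondetects(sampling)), consumption)


def test_forecast_all_schema_and_leakage(small_predictions):
    p = small_predictions
    assert set(p.columns) == {
        "city", "indicator", "week", "model", "split", "y_true", "y_pred"
    }
    assert set(p["model"]) == {"lstm", "xgb"}
    for (_, _, _), g in p.groupby(["city", "indicator", "model"]):
        tr = g[g["split"] == "train"]["week"]
        te = g[g["split"] == "test"]["week"]
        assert tr.max() < te.min()


def test_forecast_predictions_on_original_scale(small_predictions):
    """Test predictions stay within the observed range +- 50% slack."""
    for (_, _, _), g in small_predictions.groupby(["city", "indicator", "model"]):
        lo, hi = g["y_true"].min(), g["y_true"].max()
        slack = 0.5 * (hi - lo) if hi > lo else 0.5 * abs(hi)
        assert (g["y_pred"] >= lo - slack).all()
        assert (g["y_pred"] <= hi + slack).all()
        assert np.isfinite(g["y_pred"]).all()
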