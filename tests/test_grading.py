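"""Normalization, SSE/elbow, cluster-to-level ranking and recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from oilrisk import RiskGrader, assign_level, elbow_k, fit_grade_model, normalize, sse
from oilrisk.exceptions import DegenerateScaleError, ValidationError
from oilrisk.grading import IndicatorNormalizer, sse_curve
from sklearn.exceptions import NotFittedError


def _triples(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=["ilcr", "moe", "nipi"])


# ---------------------------------------------------------------- normalize
def test_two_points_hit_endpoints():
    pts, _ = normalize(_triples([[1, 10, 3], [2, 20, 4]]))
    # moe axis reflected: larger raw moe -> smaller normalized value
    np.testing.assert_allclose(pts, [[0, 1, 0], [1, 0, 1]])


def test_largest_moe_maps_to_zero(default_triples):
    pts, _ = normalize(default_triples)
    safest = default_triples["moe"].to_numpy().argmax()
    assert pts[safest, 1] == 0.0


def test_roundtrip_on_training_data(default_triples):
    pts, norm = normalize(default_triples)
    np.testing.assert_allclose(norm.transform(default_triples), pts)
    assert pts.min() >= 0.0 and pts.max() <= 1.0


def test_constant_indicator_rejected():
    with pytest.raises(DegenerateScaleError):
        normalize(_triples([[1, 10, 3], [2, 10, 4]]))


def test_out_of_range_inputs_clipped(default_triples):
    _, norm = normalize(default_triples)
    big = _triples([[1e6, 1e-9, 1e6]])
    out = norm.transform(big)
    np.testing.assert_allclose(out, [[1, 1, 1]])


# --------------------------------------------------------------------- sse
def test_sse_zero_at_centers():
    pts = np.array([[0.0, 0, 0], [1, 1, 1]])
    assert sse(pts, pts, [0, 1]) == 0.0


def test_sse_hand_value():
    pts = np.array([[0.0], [2.0]])
    assert sse(pts, np.array([[1.0]]), [0, 0]) == 2.0


def test_sse_matches_brute_force(rng):
    pts = rng.random((40, 3))
    centers = rng.random((3, 3))
    assign = rng.integers(0, 3, size=40)
    brute = sum(
        np.sum((pts[i] - centers[assign[i]]) ** 2) for i in range(len(pts))
    )
    assert sse(pts, centers, assign) == pytest.approx(brute, rel=1e-12)


# ------------------------------------------------------------------- elbow
def test_sse_curve_non_increasing(default_triples):
    pts, _ = normalize(default_triples)
    curve = sse_curve(pts, range(1, 9), seed=0)
    vals = [curve[k] for k in range(1, 9)]
    assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


def test_elbow_recovers_three_planted_levels(default_triples):
    pts, _ = normalize(default_triples)
    k, curve = elbow_k(pts, range(1, 9), seed=42)
    assert k == 3
    assert set(curve) == set(range(1, 9))


def test_elbow_needs_three_candidates(default_triples):
    pts, _ = normalize(default_triples)
    with pytest.raises(ValidationError):
        elbow_k(pts, [2, 3], seed=0)


def test_single_blob_curve_is_flat(rng):
    """One tight blob: successive SSE ratios stay small (no elbow
    structure), unlike the ~4x per-step drops of clustered data."""
    blob = rng.normal(0.5, 0.02, size=(300, 3))
    curve = sse_curve(blob, range(1, 7), seed=1)
    ratios = [curve[k] / curve[k + 1] for k in range(1, 6)]
    assert max(ratios) < 2.0


# ----------------------------------------------------------------- grading
def test_planted_level_recovery(default_triples, truth_levels):
    model = fit_grade_model(default_triples, k=3, seed=0)
    ari = adjusted_rand_score(truth_levels, model.labels_)
    assert ari > 0.9
    assert (model.labels_ == truth_levels).mean() >= 0.9


def test_k1_collapses_to_one_level(default_triples):
    model = RiskGrader(k=1, random_state=0).fit(default_triples)
    assert len(set(model.labels_)) == 1


def test_duplicating_points_leaves_centers_unchanged(default_triples):
    a = fit_grade_model(default_triples, k=3, seed=0)
    doubled = pd.concat([default_triples, default_triples], ignore_index=True)
    b = fit_grade_model(doubled, k=3, seed=0)
    ca = a.centers_[np.lexsort(a.centers_.T)]
    cb = b.centers_[np.lexsort(b.centers_.T)]
    np.testing.assert_allclose(ca, cb, atol=1e-7)


def test_centers_inside_unit_cube(default_triples):
    model = fit_grade_model(default_triples, k=3, seed=0)
    assert model.centers_.min() >= -1e-12 and model.centers_.max() <= 1 + 1e-12


def test_level_order_is_bijection(default_triples):
    model = fit_grade_model(default_triples, k=3, seed=0)
    assert sorted(model.level_order_) == [0, 1, 2]


def test_library_fit_beats_random_centers(default_triples, rng):
    """Brute-force sanity bound: k-means SSE <= best of 1,000 random
    center triples."""
    pts, _ = normalize(default_triples)
    model = fit_grade_model(default_triples, k=3, seed=0)
    fitted = model.kmeans_.inertia_
    best_random = np.inf
    for _ in range(1000):
        centers = rng.random((3, 3))
        d = ((pts[:, None, :] - centers[None]) ** 2).sum(-1)
        best_random = min(best_random, float(d.min(axis=1).sum()))
    assert fitted <= best_random


# ------------------------------------------------------------ assign_level
def test_center_maps_to_own_level(default_triples):
    model = fit_grade_model(default_triples, k=3, seed=0)
    inv = _inverse_normalize(model, model.centers_)
    for center_raw, cluster in zip(inv, range(3)):
        expected = model.level_names_[model.level_order_[cluster]]
        assert assign_level(model, center_raw) == expected


def test_extreme_triple_gets_highest_level(default_triples):
    model = fit_grade_model(default_triples, k=3, seed=0)
    probe = [
        default_triples["ilcr"].max() * 10,
        default_triples["moe"].min() / 10,  # tiny margin = risky
        default_triples["nipi"].max() * 10,
    ]
    assert assign_level(model, probe) == "high"


def test_assignment_invariant_to_center_order(default_triples):
    model = fit_grade_model(default_triples, k=3, seed=0)
    d = model.to_dict()
    perm = [2, 0, 1]
    d["centers"] = [d["centers"][j] for j in perm]
    d["level_order"] = [d["level_order"][j] for j in perm]
    permuted = RiskGrader.from_dict(d)
    np.testing.assert_array_equal(
        model.predict(default_triples), permuted.predict(default_triples)
    )


def test_unfitted_model_raises():
    with pytest.raises(NotFittedError):
        RiskGrader(k=3).predict(_triples([[1, 2, 3]]))


def _inverse_normalize(model, pts):
    norm = model.normalizer_
    s = np.array(pts, dtype=float, copy=True)
    s[:, norm.reflect_] = 1.0 - s[:, norm.reflect_]
    return norm.data_min_ + s * (norm.data_max_ - norm.data_min_)


def test_monotone_risk_along_center_polyline(default_triples):
    """Walking the polyline through the ordered centers never lowers the
    assigned ordinal level."""
    model = fit_grade_model(default_triples, k=3, seed=0)
    order = np.argsort(model.level_order_)  # clusters from low to high
    path = model.centers_[order]
    probes = []
    for a, b in zip(path[:-1], path[1:]):
        for t in np.linspace(0, 1, 25):
            probes.append(a + t * (b - a))
    raw = _inverse_normalize(model, np.array(probes))
    ranks = model.predict_rank(raw)
    assert np.all(np.diff(ranks) >= 0)
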