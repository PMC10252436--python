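"""Risk grading: normalize indicator triples, pick k by the elbow rule,
fit k-means, and rank clusters into ordered risk levels.

Raw (ILCR, MOE, NIPI) triples live on wildly different scales and MOE is
risk-*decreasing* (a large margin of exposure is safe).  Each indicator is
min–max scaled to [0, 1] and the MOE axis reflected (1 − scaled), so that
in the normalized space every axis is risk-increasing and the Euclidean
distance of a cluster center from the origin is a coherent risk ranking:
the further a center sits from the origin, the higher its level.

The number of clusters is chosen by the elbow criterion on the within-
cluster sum of squared errors (SSE): fit k-means for each candidate k and
select the k of maximum discrete curvature of the SSE profile.  Curvature
is measured on log SSE — the second difference
log SSE(k−1) − 2·log SSE(k) + log SSE(k+1) over interior candidates —
because SSE curves decay roughly geometrically, so the second difference
of the *raw* curve is dominated by its first points and would flag the
smallest interior k on almost any data; the log form is scale-invariant
and peaks where the relative per-step improvement collapses, which is
what the visual elbow shows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateScaleError, ValidationError
from .synthetic import LEVELS

INDICATORS = ("ilcr", "moe", "nipi")
#: Indicators for which a larger raw value means *less* risk.
RISK_DECREASING = ("moe",)


def _as_points(X) -> np.ndarray:
    """Accept a triples DataFrame (ilcr/moe/nipi columns) or an (n, 3) array."""
    if isinstance(X, pd.DataFrame):
        return X.loc[:, list(INDICATORS)].to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(INDICATORS):
        raise ValidationError(
            f"expected an (n, {len(INDICATORS)}) indicator array, got {arr.shape}"
        )
    return arr


class IndicatorNormalizer(TransformerMixin, BaseEstimator):
    """Min–max scaling per indicator with risk-decreasing axes reflected.

    After :meth:`transform` every coordinate lies in [0, 1] (out-of-range
    inputs are clipped) and larger always means riskier.
    """

    def fit(self, X, y=None):
        pts = _as_points(X)
        self.data_min_ = pts.min(axis=0)
        self.data_max_ = pts.max(axis=0)
        span = self.data_max_ - self.data_min_
        for j, name in enumerate(INDICATORS):
            if span[j] == 0:
                raise DegenerateScaleError(
                    f"indicator '{name}' has a single distinct value"
                )
        self.reflect_ = np.array([n in RISK_DECREASING for n in INDICATORS])
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "data_min_")
        pts = _as_points(X)
        scaled = (pts - self.data_min_) / (self.data_max_ - self.data_min_)
        scaled = np.clip(scaled, 0.0, 1.0)
        scaled[:, self.reflect_] = 1.0 - scaled[:, self.reflect_]
        return scaled


def normalize(triples) -> tuple[np.ndarray, IndicatorNormalizer]:
    """Functional form: normalized points plus the fitted scaler."""
    norm = IndicatorNormalizer().fit(triples)
    return norm.transform(triples), norm


def sse(points: np.ndarray, centers: np.ndarray, assignment: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances to the assigned
    centers (the k-means objective)."""
    points = np.asarray(points, dtype=float)
    centers = np.asarray(centers, dtype=float)
    diff = points - centers[np.asarray(assignment, dtype=int)]
    return float(np.sum(diff**2))


def _fit_kmeans(points: np.ndarray, k: int, seed, n_init: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)


def sse_curve(
    points: np.ndarray, k_range, seed=None, n_init: int = 10
) -> dict[int, float]:
    """SSE per candidate k, guaranteed non-increasing.

    Besides the usual k-means++ restarts, each k also tries a nested-capacity
    warm start — the previous k's best centers plus the point farthest from
    them — whose Lloyd refinement can only lower the objective, so
    SSE(k) <= SSE(k−1) holds exactly.
    """
    ks = sorted(k_range)
    if ks[0] < 1 or ks[-1] > len(points):
        raise ValidationError("k_range must lie within [1, n_points]")
    curve: dict[int, float] = {}
    prev: KMeans | None = None
    for k in ks:
        km = _fit_kmeans(points, k, seed, n_init)
        if prev is not None and k == prev.n_clusters + 1:
            centers = prev.cluster_centers_
            d2 = ((points[:, None, :] - centers[None]) ** 2).sum(-1).min(1)
            init = np.vstack([centers, points[np.argmax(d2)]])
            warm = KMeans(n_clusters=k, init=init, n_init=1).fit(points)
            if warm.inertia_ < km.inertia_:
                km = warm
        curve[k] = float(km.inertia_)
        prev = km
    return curve


def elbow_k(
    points: np.ndarray, k_range=range(1, 9), seed=None, n_init: int = 10
) -> tuple[int, dict[int, float]]:
    """Select k by maximum discrete curvature of the log-SSE curve.

    Returns (selected k, SSE per candidate k).  Needs at least three
    candidates so an interior second difference exists.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValidationError("elbow_k needs >= 3 candidate k values")
    curve = sse_curve(points, ks, seed=seed, n_init=n_init)
    log_sse = np.log(np.maximum([curve[k] for k in ks], 1e-300))
    best_k, best_curv = None, -np.inf
    for i in range(1, len(ks) - 1):
        curv = log_sse[i - 1] - 2 * log_sse[i] + log_sse[i + 1]
        if curv > best_curv:
            best_k, best_curv = ks[i], curv
    return int(best_k), curve


class RiskGrader(ClusterMixin, BaseEstimator):
    """k-means risk grading of (ILCR, MOE, NIPI) triples.

    Parameters
    ----------
    k : int or "auto"
        Number of clusters; "auto" selects k by the elbow criterion over
        ``k_range``.
    k_range : iterable of int
        Candidate cluster counts for the elbow sweep.
    n_init : int
        k-means++ restarts per fit.
    random_state : int or None
        Seed for center initialization.
    max_retries : int
        Refits attempted (with perturbed seeds) should a cluster come out
        empty before giving up.

    Attributes
    ----------
    k_ : selected number of clusters.
    centers_ : (k, 3) cluster centers in normalized indicator space.
    normalizer_ : the fitted :class:`IndicatorNormalizer`.
    level_order_ : level rank per cluster index (0 = lowest risk),
        assigned by ascending distance of the center from the origin.
    level_names_ : level name per rank.
    sse_curve_ : SSE per candidate k (only when k="auto").
    """

    def __init__(
        self,
        k="auto",
        k_range=range(1, 9),
        n_init: int = 10,
        random_state=None,
        max_retries: int = 5,
    ):
        self.k = k
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state
        self.max_retries = max_retries

    def fit(self, X, y=None):
        self.normalizer_ = IndicatorNormalizer().fit(X)
        pts = self.normalizer_.transform(X)

        if self.k == "auto":
            self.k_, self.sse_curve_ = elbow_k(
                pts, self.k_range, seed=self.random_state, n_init=self.n_init
            )
        else:
            self.k_ = int(self.k)
            if self.k_ < 1:
                raise ValidationError("k must be >= 1")
            self.sse_curve_ = None

        seed = self.random_state
        for attempt in range(self.max_retries + 1):
            km = _fit_kmeans(pts, self.k_, seed, self.n_init)
            if len(np.unique(km.labels_)) == self.k_:
                break
            seed = None if seed is None else seed + 1000003 * (attempt + 1)
        else:
            raise ValidationError("k-means produced an empty cluster repeatedly")

        self.kmeans_ = km
        self.centers_ = km.cluster_centers_
        dist = np.linalg.norm(self.centers_, axis=1)
        self.level_order_ = np.argsort(np.argsort(dist))  # cluster -> rank
        self.level_names_ = self._names(self.k_)
        self.labels_ = self._levels_from_clusters(km.labels_)
        return self

    @staticmethod
    def _names(k: int) -> tuple[str, ...]:
        if k == 3:
            return LEVELS
        if k == 2:
            return (LEVELS[0], LEVELS[2])
        if k == 1:
            return (LEVELS[0],)
        return tuple(f"level{i + 1}" for i in range(k))

    def _levels_from_clusters(self, clusters: np.ndarray) -> np.ndarray:
        ranks = self.level_order_[clusters]
        return np.asarray(self.level_names_)[ranks]

    def _check_fitted(self):
        try:
            check_is_fitted(self, "centers_")
        except NotFittedError:
            raise NotFittedError("RiskGrader is not fitted") from None

    def predict(self, X) -> np.ndarray:
        """Risk level of each triple: nearest center after normalization
        (clipped to [0,1]^3); ties go to the higher level."""
        self._check_fitted()
        pts = self.normalizer_.transform(X)
        d = np.linalg.norm(pts[:, None, :] - self.centers_[None], axis=2)
        # scan centers from highest to lowest rank so argmin ties resolve high
        order = np.argsort(-self.level_order_)
        nearest = order[np.argmin(d[:, order], axis=1)]
        return self._levels_from_clusters(nearest)

    def predict_rank(self, X) -> np.ndarray:
        """Ordinal level (0 = lowest risk) of each triple."""
        self._check_fitted()
        names = list(self.level_names_)
        return np.array([names.index(lv) for lv in self.predict(X)])

    @classmethod
    def from_dict(cls, d: dict) -> "RiskGrader":
        """Rebuild a fitted grader from :meth:`to_dict` output (enough state
        to normalize and assign levels; the k-means object itself is not
        restored)."""
        model = cls(k=d["k"])
        norm = IndicatorNormalizer()
        norm.data_min_ = np.asarray(d["norm_params"]["min"], dtype=float)
        norm.data_max_ = np.asarray(d["norm_params"]["max"], dtype=float)
        norm.reflect_ = np.asarray(d["norm_params"]["reflect"], dtype=bool)
        model.normalizer_ = norm
        model.k_ = int(d["k"])
        model.centers_ = np.asarray(d["centers"], dtype=float)
        model.level_order_ = np.asarray(d["level_order"], dtype=int)
        model.level_names_ = tuple(d["level_names"])
        model.sse_curve_ = d.get("sse_curve")
        return model

    def to_dict(self) -> dict:
        """JSON-serializable model state (centers, scaling, level order)."""
        self._check_fitted()
        return {
            "k": int(self.k_),
            "centers": self.centers_.tolist(),
            "norm_params": {
                "min": self.normalizer_.data_min_.tolist(),
                "max": self.normalizer_.data_max_.tolist(),
                "reflect": self.normalizer_.reflect_.tolist(),
            },
            "level_order": self.level_order_.tolist(),
            "level_names": list(self.level_names_),
            "sse_curve": self.sse_curve_,
        }


def fit_grade_model(triples, k: int = 3, seed=None) -> RiskGrader:
    """Fit a :class:`RiskGrader` with a fixed cluster count."""
    return RiskGrader(k=k, random_state=seed).fit(triples)


def assign_level(model: RiskGrader, triple) -> str:
    """Level of a single (ilcr, moe, nipi) triple under a fitted model."""
    arr = np.asarray(triple, dtype=float).reshape(1, -1)
    return str(model.predict(arr)[0])
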