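"""Synthetic sampling and consumption data with a planted risk structure.

The generator emulates a national contaminant-surveillance campaign:
prefecture-level cities sampled weekly for benzo[a]pyrene (BaP) in edible
oil, with left-censoring below a fixed limit of detection (LOD), plus a
per-city consumption table (daily oil intake, body weight).  Each city is
assigned one of three latent concentration regimes (low / medium / high);
the assignment table is returned so that grading-recovery tests can compare
recovered risk levels against the planted truth.

Concentrations are lognormal around the regime mean.  When a target
non-detect fraction is requested, draws are censored at the LOD; if the
natural left-tail mass differs from the target by more than 0.05 the
lognormal location is shifted by a common log-offset solved analytically
from the mixture CDF, which preserves regime ordering and all concentration
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .exceptions import ConfigurationError

#: Ordered risk-level names, lowest first.
LEVELS = ("low", "medium", "high")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic surveillance campaign.

    Defaults mirror the scale of a national sampling year (53 weekly
    sampling rounds, LOD 0.2 μg/kg, a sub-60% non-detect share) at a size
    that runs in seconds.
    """

    n_provinces: int = 4
    cities_per_province: int = 3
    n_weeks: int = 53
    lod: float = 0.2  # μg/kg
    nondetect_frac: float = 0.4
    level_means: tuple[float, float, float] = (0.5, 2.0, 6.0)  # μg/kg
    level_props: tuple[float, float, float] = (0.5, 0.35, 0.15)
    noise_cv: float = 0.4
    samples_per_city_week: int = 8
    intake_range: tuple[float, float] = (0.04, 0.05)  # kg/d
    body_weight: float = 60.0  # kg
    seed: int = 0

    def validate(self) -> None:
        if self.n_provinces < 1:
            raise ConfigurationError("n_provinces must be >= 1")
        if self.cities_per_province < 1:
            raise ConfigurationError("cities_per_province must be >= 1")
        if self.n_weeks < 8:
            raise ConfigurationError("n_weeks must be >= 8 (forecasting needs windows)")
        if not self.lod > 0:
            raise ConfigurationError("lod must be > 0")
        if not (0 <= self.nondetect_frac < 1):
            raise ConfigurationError("nondetect_frac must lie in [0, 1)")
        means = np.asarray(self.level_means, dtype=float)
        if means.shape != (3,) or not np.all(np.diff(means) > 0) or means[0] <= 0:
            raise ConfigurationError(
                "level_means must be three strictly increasing positive values"
            )
        props = np.asarray(self.level_props, dtype=float)
        if props.shape != (3,) or np.any(props <= 0):
            raise ConfigurationError("level_props must be three positive proportions")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("level_props must sum to 1 within 1e-9")
        if not self.noise_cv > 0:
            raise ConfigurationError("noise_cv must be > 0")
        if self.samples_per_city_week < 1:
            raise ConfigurationError("samples_per_city_week must be >= 1")
        lo, hi = self.intake_range
        if not (0 < lo <= hi):
            raise ConfigurationError("intake_range must satisfy 0 < low <= high")
        if not self.body_weight > 0:
            raise ConfigurationError("body_weight must be > 0")

    @property
    def n_cities(self) -> int:
        return self.n_provinces * self.cities_per_province


def _level_counts(props: np.ndarray, n_cities: int) -> np.ndarray:
    """Largest-remainder apportionment of cities to levels.

    Every level receives at least one city whenever n_cities >= 3, so the
    planted structure always contains all three regimes.
    """
    if n_cities < 3:
        # degenerate campaign: fill from the low level upward
        counts = np.zeros(3, dtype=int)
        counts[:n_cities] = 1
        return counts
    counts = np.ones(3, dtype=int)
    remaining = n_cities - 3
    quotas = props * remaining
    counts += np.floor(quotas).astype(int)
    leftovers = remaining - int(np.floor(quotas).sum())
    order = np.argsort(-(quotas - np.floor(quotas)))
    for i in range(leftovers):
        counts[order[i % 3]] += 1
    return counts


def _censoring_shift(
    mus: np.ndarray, sigma: float, weights: np.ndarray, lod: float, target: float
) -> float:
    """Common log-space location offset so the expected fraction of draws
    below ``lod`` equals ``target``.

    The mixture left-tail mass sum_l w_l * Phi((ln lod - mu_l - d) / sigma)
    is strictly increasing in d, so a unique root exists; returns 0 when the
    natural mass is already within 0.05 of the target.
    """

    def frac(delta: float) -> float:
        return float(weights @ norm.cdf((np.log(lod) - mus - delta) / sigma))

    if abs(frac(0.0) - target) <= 0.05:
        return 0.0
    lo, hi = -50.0, 50.0
    return float(brentq(lambda d: frac(d) - target, lo, hi, xtol=1e-12))


def generate(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (sampling, consumption, truth) tables.

    Returns
    -------
    sampling : DataFrame with columns province, city, week, concentration
        (μg/kg; NaN for non-detects) and detected (bool).
    consumption : DataFrame with columns city, intake_kg_per_day,
        body_weight_kg — one row per city.
    truth : DataFrame with columns city, week, level — the planted latent
        risk level, constant across weeks for each city.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    provinces = [f"P{p + 1:02d}" for p in range(cfg.n_provinces)]
    cities = [
        (prov, f"{prov}-C{c + 1:02d}")
        for prov in provinces
        for c in range(cfg.cities_per_province)
    ]
    n_cities = len(cities)

    props = np.asarray(cfg.level_props, dtype=float)
    counts = _level_counts(props, n_cities)
    city_levels = np.repeat(np.arange(3), counts)[:n_cities]
    rng.shuffle(city_levels)

    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    mus = np.log(np.asarray(cfg.level_means, dtype=float)) - sigma**2 / 2

    if cfg.nondetect_frac > 0:
        weights = np.bincount(city_levels, minlength=3) / n_cities
        delta = _censoring_shift(mus, sigma, weights, cfg.lod, cfg.nondetect_frac)
    else:
        delta = 0.0

    m = cfg.samples_per_city_week
    rows_prov, rows_city, rows_week = [], [], []
    conc_blocks = []
    for (prov, city), lvl in zip(cities, city_levels):
        draws = rng.lognormal(mus[lvl] + delta, sigma, size=cfg.n_weeks * m)
        conc_blocks.append(draws)
        rows_prov.extend([prov] * cfg.n_weeks * m)
        rows_city.extend([city] * cfg.n_weeks * m)
        rows_week.extend(np.repeat(np.arange(1, cfg.n_weeks + 1), m))
    conc = np.concatenate(conc_blocks)

    if cfg.nondetect_frac > 0:
        detected = conc >= cfg.lod
    else:
        detected = np.ones_like(conc, dtype=bool)
    sampling = pd.DataFrame(
        {
            "province": rows_prov,
            "city": rows_city,
            "week": np.asarray(rows_week, dtype=int),
            "concentration": np.where(detected, conc, np.nan),
            "detected": detected,
        }
    )

    intake = rng.uniform(*cfg.intake_range, size=n_cities)
    consumption = pd.DataFrame(
        {
            "city": [c for _, c in cities],
            "intake_kg_per_day": intake,
            "body_weight_kg": cfg.body_weight,
        }
    )

    truth = pd.DataFrame(
        {
            "city": np.repeat([c for _, c in cities], cfg.n_weeks),
            "week": np.tile(np.arange(1, cfg.n_weeks + 1), n_cities),
            "level": np.repeat([LEVELS[l] for l in city_levels], cfg.n_weeks),
        }
    )
    return sampling, consumption, truth


def write_outputs(
    sampling: pd.DataFrame,
    consumption: pd.DataFrame,
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write sampling.csv, consumption.csv and truth.csv (UTF-8, headered,
    '.' decimal separator; empty concentration field marks a non-detect)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sampling": out / "sampling.csv",
        "consumption": out / "consumption.csv",
        "truth": out / "truth.csv",
    }
    sampling.to_csv(paths["sampling"], index=False)
    consumption.to_csv(paths["consumption"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths


def read_sampling(path: str | Path) -> pd.DataFrame:
    """Read a sampling.csv, restoring the detected flag and NaN non-detects."""
    df = pd.read_csv(path)
    df["detected"] = df["detected"].astype(bool)
    return df
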