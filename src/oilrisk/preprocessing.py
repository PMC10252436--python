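"""Non-detect substitution and city-week aggregation.

Left-censored laboratory results (below the limit of detection, LOD) are
replaced following the WHO substitution convention: when the non-detect
share of the whole dataset is at most 60%, each non-detect is valued at
LOD/2; above 60% it is valued at the LOD itself.  The share is computed
over the entire input, not per city — one global rule for the campaign.

Valued records are then aggregated to one summary per (city, week): the
median (feeds the cancer-risk index), the mean (feeds exposure / margin of
exposure) and the maximum (feeds the integrated pollution index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError


@dataclass(frozen=True)
class CensoringPolicy:
    """LOD and the fixed 60% switching threshold of the substitution rule."""

    lod: float = 0.2  # μg/kg
    threshold_frac: float = 0.60

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise ConfigurationError("lod must be > 0")
        if self.threshold_frac != 0.60:
            raise ConfigurationError("threshold_frac is fixed at 0.60")


def substitute_nondetects(
    records: pd.DataFrame, policy: CensoringPolicy = CensoringPolicy()
) -> pd.DataFrame:
    """Value every non-detect at LOD/2 or LOD depending on the global
    non-detect share; detected values pass through unchanged.

    Parameters
    ----------
    records : DataFrame with columns city, week, concentration, detected
        (province optional).  Non-detects carry NaN concentration.

    Returns
    -------
    DataFrame of the same shape with all rows detected and valued.
    """
    if len(records) == 0:
        raise ValidationError("substitute_nondetects: empty input")
    detected = records["detected"].to_numpy(dtype=bool)
    conc = records["concentration"].to_numpy(dtype=float)
    if np.any(conc[detected] < 0):
        raise ValidationError("negative concentration in detected records")

    q = 1.0 - detected.mean()
    fill = policy.lod / 2 if q <= policy.threshold_frac else policy.lod

    out = records.copy()
    out["concentration"] = np.where(detected, conc, fill)
    out["detected"] = True
    return out


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate valued records to per-(city, week) summaries.

    Returns a DataFrame with columns city, week, median_conc, mean_conc,
    max_conc, n_samples (concentrations in μg/kg).  (city, week) pairs with
    no samples are simply absent; gap handling is deferred to forecasting.
    """
    if len(records) == 0:
        raise ValidationError("summarize: empty input")
    conc = records["concentration"].to_numpy(dtype=float)
    if np.any(~np.isfinite(conc)):
        raise ValidationError("summarize requires valued records (no NaN)")
    if np.any(conc < 0):
        raise ValidationError("negative concentration")

    grouped = records.groupby(["city", "week"], sort=True)["concentration"]
    out = grouped.agg(
        median_conc="median", mean_conc="mean", max_conc="max", n_samples="size"
    ).reset_index()
    return out
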