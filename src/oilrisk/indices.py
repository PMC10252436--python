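"""Risk indices for a carcinogenic food contaminant.

Three complementary indicators are computed per city-week:

* **ILCR** — Incremental Lifetime Cancer Risk,
  ``ILCR = C·TEF·Ir·Ep·SF·CF / (BW·TA)``, the added lifetime probability of
  cancer from chronic dietary exposure.  C is the median contaminant
  concentration (mg/kg), TEF the toxic-equivalency factor, Ir daily oil
  intake (kg/d), Ep exposure frequency (d/a), SF the carcinogenic slope
  factor (kg·d/mg), CF a units conversion factor, BW body weight (kg) and
  TA the averaging time (d).  US EPA bands: below 1e-6 negligible, 1e-6 to
  1e-4 (inclusive) acceptable, above 1e-4 non-negligible.

* **MOE** — Margin of Exposure, ``MOE = BMDL10 / Exp`` with
  ``Exp = Fi·Ci / (BW·1000)`` the daily intake of contaminant per kg body
  weight (mg/(kg·d); Ci is the mean concentration in μg/kg, hence the 1000).
  EFSA convention: MOE strictly above 10,000 is of very low concern.

* **NIPI** — Nemerow Integrated Pollution Index, the quadratic mean of the
  maximum and average single-sample pollution indices ``P_i = X_i / Sj``
  relative to the regulatory limit Sj (mg/kg).

The defaults are the standard constants for benzo[a]pyrene in edible oil
(TEF 1, SF 7.3 kg·d/mg, BMDL10 0.07 mg/(kg·d), Sj 0.01 mg/kg, BW 60 kg);
all are overridable so the pipeline can serve other contaminants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    MissingConsumptionError,
    ValidationError,
    ZeroExposureError,
)

ILCR_NEGLIGIBLE = "negligible"
ILCR_ACCEPTABLE = "acceptable"
ILCR_NON_NEGLIGIBLE = "non-negligible"

MOE_VERY_LOW_RISK = "very-low-risk"
MOE_ATTENTION = "attention-required"


@dataclass(frozen=True)
class IlcrParams:
    """Constants of the lifetime cancer-risk formula.

    ``ed`` (exposure duration, years) is part of the standard parameter set
    and is retained for documentation, but the formula as used here contains
    only ``ep`` and ``ta`` (= ed·ep under the defaults).
    """

    tef: float = 1.0
    ep: float = 365.0  # d/a
    ed: float = 70.0  # a
    sf: float = 7.3  # kg·d/mg
    cf: float = 1e-6
    bw: float = 60.0  # kg
    ta: float = 70.0 * 365.0  # d

    def __post_init__(self) -> None:
        for name in ("tef", "ep", "ed", "sf", "cf", "bw", "ta"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"IlcrParams.{name} must be > 0")


@dataclass(frozen=True)
class MoeParams:
    bmdl10: float = 0.07  # mg/(kg·d)
    bw: float = 60.0  # kg

    def __post_init__(self) -> None:
        if not self.bmdl10 > 0:
            raise ConfigurationError("MoeParams.bmdl10 must be > 0")
        if not self.bw > 0:
            raise ConfigurationError("MoeParams.bw must be > 0")


@dataclass(frozen=True)
class NipiParams:
    sj: float = 0.01  # mg/kg, national limit

    def __post_init__(self) -> None:
        if not self.sj > 0:
            raise ConfigurationError("NipiParams.sj must be > 0")


def ilcr(c: float, ir: float, p: IlcrParams = IlcrParams()) -> float:
    """Incremental lifetime cancer risk for concentration ``c`` (mg/kg) and
    daily intake ``ir`` (kg/d).  Linear in both ``c`` and ``ir``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValidationError("ilcr: concentration must be >= 0")
    if np.any(np.asarray(ir, dtype=float) <= 0):
        raise ValidationError("ilcr: intake must be > 0")
    val = c * p.tef * ir * p.ep * p.sf * p.cf / (p.bw * p.ta)
    return float(val) if np.isscalar(ir) and val.ndim == 0 else val


def ilcr_category(x: float) -> str:
    """US EPA banding of an ILCR value; both ends of the acceptable band
    (1e-6 and 1e-4) are inclusive."""
    if x < 0:
        raise ValidationError("ilcr_category: value must be >= 0")
    if x < 1e-6:
        return ILCR_NEGLIGIBLE
    if x <= 1e-4:
        return ILCR_ACCEPTABLE
    return ILCR_NON_NEGLIGIBLE


def exposure(fi: float, ci: float, bw: float = 60.0) -> float:
    """Daily contaminant intake per kg body weight, mg/(kg·d).

    ``fi``: oil consumption kg/d; ``ci``: mean concentration μg/kg;
    ``bw``: body weight kg.
    """
    if np.any(np.asarray(fi) <= 0):
        raise ValidationError("exposure: consumption must be > 0")
    if np.any(np.asarray(ci) < 0):
        raise ValidationError("exposure: concentration must be >= 0")
    if np.any(np.asarray(bw) <= 0):
        raise ValidationError("exposure: body weight must be > 0")
    return fi * ci / (bw * 1000.0)


def moe(exp_val: float, p: MoeParams = MoeParams()) -> float:
    """Margin of exposure BMDL10 / Exp.  Zero exposure raises
    :class:`ZeroExposureError` — the margin is undefined, not infinite."""
    if np.any(np.asarray(exp_val) < 0):
        raise ValidationError("moe: exposure must be >= 0")
    if np.any(np.asarray(exp_val) == 0):
        raise ZeroExposureError("moe undefined at zero exposure")
    return p.bmdl10 / exp_val


def moe_category(moe_val: float) -> str:
    """EFSA interpretation: strictly above 10,000 → very low risk; at or
    below 10,000 → requires attention."""
    return MOE_VERY_LOW_RISK if moe_val > 10_000 else MOE_ATTENTION


def nipi(concs, p: NipiParams = NipiParams()) -> float:
    """Nemerow integrated pollution index of a concentration collection
    (mg/kg): sqrt((max(P)^2 + mean(P)^2) / 2) with P_i = X_i / Sj."""
    arr = np.asarray(concs, dtype=float)
    if arr.size == 0:
        raise ValidationError("nipi: empty concentration collection")
    if np.any(arr < 0):
        raise ValidationError("nipi: concentrations must be >= 0")
    pollution = arr / p.sj
    return float(np.sqrt((pollution.max() ** 2 + pollution.mean() ** 2) / 2.0))


def compute_triples(
    summaries: pd.DataFrame,
    consumption: pd.DataFrame,
    ilcr_params: IlcrParams = IlcrParams(),
    moe_params: MoeParams = MoeParams(),
    nipi_params: NipiParams = NipiParams(),
) -> pd.DataFrame:
    """One (ILCR, MOE, NIPI) triple per city-week summary.

    ILCR uses the median concentration (μg/kg → mg/kg), MOE the mean
    concentration in μg/kg, NIPI the group's samples in mg/kg.  Because the
    pollution indices are the samples divided by the fixed limit Sj, the
    group's mean and max index equal mean_conc/Sj and max_conc/Sj, so NIPI
    is computed exactly from the stored summary statistics.

    Returns a DataFrame with columns city, week, ilcr, moe, nipi.
    """
    cons = consumption.set_index("city")
    missing = set(summaries["city"]) - set(cons.index)
    if missing:
        raise MissingConsumptionError(
            f"no consumption record for city: {sorted(missing)[0]}"
        )

    intake = cons.loc[summaries["city"], "intake_kg_per_day"].to_numpy(float)
    bw = cons.loc[summaries["city"], "body_weight_kg"].to_numpy(float)

    median_mg = summaries["median_conc"].to_numpy(float) / 1000.0
    mean_ug = summaries["mean_conc"].to_numpy(float)
    mean_mg = mean_ug / 1000.0
    max_mg = summaries["max_conc"].to_numpy(float) / 1000.0

    ilcr_vals = ilcr(median_mg, intake, ilcr_params)
    exp_vals = exposure(intake, mean_ug, bw)
    moe_vals = moe(exp_vals, moe_params)
    p_ave = mean_mg / nipi_params.sj
    p_max = max_mg / nipi_params.sj
    nipi_vals = np.sqrt((p_max**2 + p_ave**2) / 2.0)

    return pd.DataFrame(
        {
            "city": summaries["city"].to_numpy(),
            "week": summaries["week"].to_numpy(),
            "ilcr": ilcr_vals,
            "moe": moe_vals,
            "nipi": nipi_vals,
        }
    )


def province_nipi(
    records: pd.DataFrame, p: NipiParams = NipiParams()
) -> pd.Series:
    """Annual NIPI per province over the pooled valued samples (reporting
    aid; concentrations are converted μg/kg → mg/kg before applying Sj)."""
    if "province" not in records.columns:
        raise ValidationError("province_nipi requires a 'province' column")
    return records.groupby("province")["concentration"].apply(
        lambda s: nipi(s.to_numpy(float) / 1000.0, p)
    )
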