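"""Index formulas against independent single-expression oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oilrisk import (
    IlcrParams,
    MoeParams,
    NipiParams,
    compute_triples,
    exposure,
    ilcr,
    ilcr_category,
    moe,
    moe_category,
    nipi,
)
from oilrisk.exceptions import (
    MissingConsumptionError,
    ValidationError,
    ZeroExposureError,
)

finite_pos = st.floats(1e-6, 1e3, allow_nan=False, allow_infinity=False)


def test_ilcr_hand_value():
    # (0.01 * 1 * 0.05 * 365 * 7.3 * 1e-6) / (60 * 25550)
    assert ilcr(0.01, 0.05) == pytest.approx(8.690e-13, rel=1e-3)


def test_ilcr_zero_and_negative():
    assert ilcr(0.0, 0.05) == 0.0
    with pytest.raises(ValidationError):
        ilcr(-1.0, 0.05)


@given(c=finite_pos, ir=finite_pos)
def test_ilcr_degree_one_homogeneity(c, ir):
    assert ilcr(2 * c, ir) == pytest.approx(2 * ilcr(c, ir), rel=1e-12)


def test_ilcr_category_bands():
    assert ilcr_category(0.0) == "negligible"
    assert ilcr_category(9.99e-7) == "negligible"
    assert ilcr_category(1e-6) == "acceptable"  # inclusive lower bound
    assert ilcr_category(1e-4) == "acceptable"  # inclusive upper bound
    assert ilcr_category(1.001e-4) == "non-negligible"


def test_exposure_hand_value():
    assert exposure(0.05, 10.0, 60.0) == pytest.approx(0.5 / 60000, rel=1e-12)
    assert exposure(0.05, 0.0, 60.0) == 0.0


@given(fi=finite_pos, ci=finite_pos, bw=finite_pos)
def test_exposure_inverse_in_body_weight(fi, ci, bw):
    assert exposure(fi, ci, bw / 2) == pytest.approx(2 * exposure(fi, ci, bw), rel=1e-12)


def test_moe_hand_values():
    val = moe(8.3333e-6)
    assert val == pytest.approx(0.07 / 8.3333e-6, rel=1e-12)
    assert moe_category(val) == "attention-required"
    assert moe(0.07) == pytest.approx(1.0)
    # exactly 10,000 is NOT very-low-risk (strict >)
    assert moe(7e-6) == pytest.approx(10_000.0)
    assert moe_category(10_000.0) == "attention-required"
    assert moe_category(10_000.0000001) == "very-low-risk"


def test_moe_zero_exposure_is_an_error():
    with pytest.raises(ZeroExposureError):
        moe(0.0)


def test_nipi_hand_values():
    assert nipi([0.03, 0.03, 0.03]) == pytest.approx(3.0, rel=1e-12)
    # P = {0.5, 1.0}: sqrt((1 + 0.75^2)/2)
    assert nipi([0.005, 0.01]) == pytest.approx(
        np.sqrt((1.0 + 0.5625) / 2.0), rel=1e-12
    )
    with pytest.raises(ValidationError):
        nipi([])


def test_nipi_quadratic_mean_bounds(rng):
    for _ in range(100):
        concs = rng.lognormal(0, 1, size=rng.integers(1, 12))
        p = concs / 0.01
        val = nipi(concs)
        assert p.mean() - 1e-12 <= val <= p.max() + 1e-12


def test_formulas_match_independent_oracle(rng):
    """1,000 random inputs; each formula against a separately coded
    single-expression oracle at 1e-12 relative tolerance."""
    for _ in range(1000):
        c, ir, fi, ci, bw = rng.lognormal(0, 2, size=5)
        assert ilcr(c, ir) == pytest.approx(
            (c * 1 * ir * 365 * 7.3 * 1e-6) / (60 * 25550), rel=1e-12
        )
        e = exposure(fi, ci, bw)
        assert e == pytest.approx(fi * ci / (bw * 1000), rel=1e-12)
        assert moe(e) == pytest.approx(0.07 / (fi * ci / (bw * 1000)), rel=1e-12)
        concs = rng.lognormal(0, 1, size=5)
        ps = [x / 0.01 for x in concs]
        expected = ((max(ps) ** 2 + (sum(ps) / len(ps)) ** 2) / 2) ** 0.5
        assert nipi(concs) == pytest.approx(expected, rel=1e-12)


def _one_city_inputs(conc_values):
    summaries = pd.DataFrame(
        {
            "city": ["A"],
            "week": [1],
            "median_conc": [np.median(conc_values)],
            "mean_conc": [np.mean(conc_values)],
            "max_conc": [np.max(conc_values)],
            "n_samples": [len(conc_values)],
        }
    )
    consumption = pd.DataFrame(
        {"city": ["A"], "intake_kg_per_day": [0.05], "body_weight_kg": [60.0]}
    )
    return summaries, consumption


def test_compute_triples_composes_unit_ops():
    concs = [1.0, 2.0, 9.0]  # μg/kg
    summaries, consumption = _one_city_inputs(concs)
    out = compute_triples(summaries, consumption)
    row = out.iloc[0]
    assert row["ilcr"] == pytest.approx(ilcr(2.0 / 1000, 0.05), rel=1e-12)
    assert row["moe"] == pytest.approx(moe(exposure(0.05, 4.0, 60.0)), rel=1e-12)
    assert row["nipi"] == pytest.approx(nipi(np.array(concs) / 1000.0), rel=1e-12)


def test_compute_triples_missing_city_named():
    summaries, consumption = _one_city_inputs([1.0])
    consumption = consumption.assign(city=["B"])
    with pytest.raises(MissingConsumptionError) as exc:
        compute_triples(summaries, consumption)
    assert "A" in str(exc.value)


def test_compute_triples_zero_week_raises_zero_exposure():
    summaries, consumption = _one_city_inputs([0.0, 0.0])
    with pytest.raises(ZeroExposureError):
        compute_triples(summaries, consumption)


def test_compute_triples_order_invariant(default_triples, default_data):
    sampling, consumption, _ = default_data
    from oilrisk.preprocessing import substitute_nondetects, summarize

    summaries = summarize(substitute_nondetects(sampling))
    shuffled = summaries.sample(frac=1.0, random_state=8)
    out = compute_triples(shuffled, consumption)
    merged = out.merge(default_triples, on=["city", "week"], suffixes=("_a", "_b"))
    for col in ("ilcr", "moe", "nipi"):
        np.testing.assert_allclose(merged[f"{col}_a"], merged[f"{col}_b"], rtol=1e-12)


def test_province_nipi_matches_pooled_formula(default_data):
    from oilrisk.indices import province_nipi
    from oilrisk.preprocessing import substitute_nondetects

    sampling, _, _ = default_data
    valued = substitute_nondetects(sampling)
    out = province_nipi(valued)
    prov = valued[valued["province"] == "P01"]["concentration"].to_numpy() / 1000.0
    assert out["P01"] == pytest.approx(nipi(prov), rel=1e-12)
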