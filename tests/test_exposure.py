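"""GIS exposure assessment: worked examples, invariants, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from conftest import raster_fraction
from pwastox.config import WaveSpec, default_config
from pwastox.exposure import (BufferSpec, ExposureMatrix, annual_exposure,
                              buffer_fraction, build_exposure_matrix,
                              compute_annual_exposures, transform,
                              window_average)
from pwastox.simulate import gen_applications, gen_cohort, gen_landscape
from pwastox.simulate.cohort import true_exposure_summaries


def make_parcels():
    return pd.DataFrame({
        "parcel_id": ["P1", "P2"],
        "x0": [-50.0, 2000.0], "y0": [-50.0, 2000.0],
        "x1": [50.0, 2100.0], "y1": [50.0, 2100.0],
        "crop": ["cotton", "grape"],
    })


def make_addresses():
    return pd.DataFrame({
        "participant_id": ["S1"], "location": ["residential"],
        "x": [0.0], "y": [0.0], "start_year": [1980], "end_year": [2000],
    })


# ---------------------------------------------------------------------------
# buffer_fraction


def test_fraction_parcel_inside_buffer():
    assert buffer_fraction((0, 0), box(-50, -50, 50, 50)) == pytest.approx(1.0)


def test_fraction_disjoint():
    assert buffer_fraction((0, 0), box(2000, 2000, 2100, 2100)) == 0.0


def test_fraction_zero_area_raises():
    with pytest.raises(ValueError, match="zero area"):
        buffer_fraction((0, 0), box(10, 10, 10, 10))


def test_fraction_against_raster():
    # 200 x 200 m square centered 500 m from the address, radius 500
    f = buffer_fraction((0, 0), box(400, -100, 600, 100), BufferSpec(500))
    assert f == pytest.approx(raster_fraction(0, 0, 500, 400, -100, 600, 100),
                              abs=0.01)


def test_fraction_additive_over_subparcels():
    whole = buffer_fraction((0, 0), box(300, -100, 500, 100))
    left = buffer_fraction((0, 0), box(300, -100, 400, 100))
    right = buffer_fraction((0, 0), box(400, -100, 500, 100))
    assert (left + right) / 2 == pytest.approx(whole, abs=1e-6)


# ---------------------------------------------------------------------------
# annual exposure


def make_apps(pounds=100.0, acres=10.0):
    return pd.DataFrame({
        "year": [1990], "parcel_id": ["P1"], "pesticide": ["pest_a"],
        "pounds": [pounds], "acres_treated": [acres], "crop": ["cotton"],
    })


def test_annual_worked_example():
    # 100 lbs on 10 treated acres, parcel fully inside the buffer -> 10 lbs/acre
    out = annual_exposure(make_apps(), make_addresses(), make_parcels(), 1990)
    val = out.loc[out["pesticide"] == "pest_a", "lbs_per_acre"].iloc[0]
    assert val == pytest.approx(10.0, rel=1e-9)


def test_annual_no_applications_zero():
    apps = make_apps()
    apps["parcel_id"] = "P2"  # far away parcel only
    out = annual_exposure(apps, make_addresses(), make_parcels(), 1990)
    assert (out["lbs_per_acre"] == 0.0).all()


def test_annual_partial_parcel_scales_by_fraction():
    parcels = pd.DataFrame({"parcel_id": ["P1"], "x0": [400.0], "y0": [-100.0],
                            "x1": [600.0], "y1": [100.0], "crop": ["cotton"]})
    frac = buffer_fraction((0, 0), box(400, -100, 600, 100))
    out = annual_exposure(make_apps(), make_addresses(), parcels, 1990)
    val = out.loc[out["pesticide"] == "pest_a", "lbs_per_acre"].iloc[0]
    assert val == pytest.approx(10.0 * frac, rel=1e-9)


def test_annual_bad_acres_names_record():
    apps = make_apps(acres=0.0)
    with pytest.raises(ValueError, match="P1"):
        compute_annual_exposures(apps, make_addresses(), make_parcels())


def test_annual_linear_in_pounds():
    a1 = annual_exposure(make_apps(100), make_addresses(), make_parcels(), 1990)
    a2 = annual_exposure(make_apps(300), make_addresses(), make_parcels(), 1990)
    v1 = a1.loc[a1["pesticide"] == "pest_a", "lbs_per_acre"].iloc[0]
    v2 = a2.loc[a2["pesticide"] == "pest_a", "lbs_per_acre"].iloc[0]
    assert v2 == pytest.approx(3.0 * v1, rel=1e-9)


def test_annual_split_application_invariant():
    # splitting one record's pounds across two records over the same treated
    # acres leaves the summed annual value unchanged
    whole = make_apps(100.0, 10.0)
    split = pd.concat([make_apps(60.0, 10.0), make_apps(40.0, 10.0)],
                      ignore_index=True)
    w = annual_exposure(whole, make_addresses(), make_parcels(), 1990)
    s = annual_exposure(split, make_addresses(), make_parcels(), 1990)
    assert s["lbs_per_acre"].iloc[0] == pytest.approx(
        w["lbs_per_acre"].iloc[0], rel=1e-9)


def test_same_year_addresses_duration_weighted():
    # two residential addresses in 1990: 3 months near the parcel (value 10),
    # 9 months far away (value 0) -> weighted mean 2.5
    addresses = pd.DataFrame({
        "participant_id": ["S1", "S1"], "location": ["residential"] * 2,
        "x": [0.0, 5000.0], "y": [0.0, 5000.0],
        "start_year": [1990, 1990], "end_year": [1990, 1990],
        "start_month": [1, 4], "end_month": [3, 12],
    })
    annual = compute_annual_exposures(make_apps(), addresses, make_parcels())
    val = annual.loc[("S1", "residential", 1990), "pest_a"]
    assert val == pytest.approx(10.0 * 3 / 12, rel=1e-9)


# ---------------------------------------------------------------------------
# window averaging


def annual_frame(values_by_year, pid="S1", loc="residential"):
    idx = pd.MultiIndex.from_tuples(
        [(pid, loc, y) for y in values_by_year],
        names=["participant_id", "location", "year"])
    return pd.DataFrame({"pest_a": list(values_by_year.values())}, index=idx)


def participants_frame(pid="S1", index_year=2000):
    return pd.DataFrame({"participant_id": [pid], "index_year": [index_year],
                         "wave": ["wave1"]})


def test_window_constant_mean():
    annual = annual_frame({y: 4.0 for y in range(1980, 1991)})
    out = window_average(annual, participants_frame())
    assert out.loc[("S1", "residential"), "pest_a"] == pytest.approx(4.0)


def test_window_arithmetic_mean():
    annual = annual_frame({1980: 2.0, 1981: 0.0, 1982: 4.0})
    out = window_average(annual, participants_frame())
    assert out.loc[("S1", "residential"), "pest_a"] == pytest.approx(2.0)


def test_window_excludes_recent_years():
    # index year 2000, offset 10: years after 1990 must not contribute
    annual = annual_frame({1989: 1.0, 1990: 1.0, 1995: 100.0})
    out = window_average(annual, participants_frame())
    assert out.loc[("S1", "residential"), "pest_a"] == pytest.approx(1.0)
    assert out.loc[("S1", "residential"), "covered_years"] == 2


def test_window_22_covered_years_recomputation():
    rng = np.random.default_rng(4)
    # index year 2010, offset 10 -> window 1974..2000; cover 22 of those years
    years = rng.choice(np.arange(1974, 2001), size=22, replace=False)
    vals = {int(y): float(v) for y, v in zip(years, rng.uniform(0, 5, len(years)))}
    out = window_average(annual_frame(vals), participants_frame(index_year=2010))
    assert out.loc[("S1", "residential"), "pest_a"] == pytest.approx(
        np.mean(list(vals.values())), rel=1e-12)


def test_window_zero_coverage_missing_not_zero():
    # all covered years are after the window -> the participant-location is absent
    annual = annual_frame({1995: 3.0, 1996: 3.0})
    out = window_average(annual, participants_frame())
    assert ("S1", "residential") not in out.index


# ---------------------------------------------------------------------------
# transform


def test_transform_zero_maps_to_log1():
    raw = pd.Series([0.0, 1.0, 3.0], name="pest_a")
    z = transform(raw)
    logged = np.log1p(raw)
    expect = (logged - logged.mean()) / logged.std(ddof=1)
    assert np.allclose(z, expect)


def test_transform_mean_zero_sd_one():
    rng = np.random.default_rng(8)
    z = transform(pd.Series(rng.gamma(2, 3, 500), name="p"))
    assert abs(z.mean()) < 1e-9
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1e6, allow_nan=False, allow_infinity=False),
                min_size=3, max_size=40, unique=True))
def test_transform_monotone(values):
    z = transform(pd.Series(values, name="p"))
    # z sorted by increasing raw value must be non-decreasing (values closer
    # than floating-point resolution may tie after centering)
    order_raw = np.argsort(values, kind="stable")
    assert (np.diff(z.to_numpy()[order_raw]) >= -1e-12).all()


def test_transform_missing_stays_missing():
    z = transform(pd.Series([0.0, np.nan, 2.0, 5.0], name="p"))
    assert np.isnan(z.iloc[1]) and z.notna().sum() == 3


def test_transform_zero_variance():
    flat = pd.Series([2.0, 2.0, 2.0], name="pest_a")
    with pytest.raises(ValueError, match="pest_a"):
        transform(flat)
    assert transform(flat, strict=False).isna().all()


# ---------------------------------------------------------------------------
# exposure matrix


def matrix_from(raw_res, raw_work=None):
    raw = {"residential": raw_res}
    if raw_work is not None:
        raw["workplace"] = raw_work
    participants = pd.DataFrame({
        "participant_id": list(raw_res.index), "wave": "wave1",
        "index_year": 2000, "case": 0})
    return ExposureMatrix(raw=raw, z={k: np.log1p(v) for k, v in raw.items()},
                          covered=pd.DataFrame(), participants=participants,
                          pesticides=list(raw_res.columns))


def test_exposed_counts_and_inclusion_boundary():
    n = 40
    raw = pd.DataFrame({
        "common": [1.0] * 30 + [0.0] * 10,
        "boundary": [2.0] * 25 + [0.0] * 15,
        "rare": [1.0] * 5 + [0.0] * 35,
        "absent": [0.0] * n,
    }, index=[f"S{i}" for i in range(n)])
    expo = matrix_from(raw)
    counts = expo.exposed_counts()
    assert counts.to_dict() == {"common": 30, "boundary": 25, "rare": 5,
                                "absent": 0}
    mask = expo.inclusion_mask(25)
    assert mask.to_dict() == {"common": True, "boundary": True, "rare": False,
                              "absent": False}


def test_exposed_either_location():
    res = pd.DataFrame({"p": [1.0, 0.0, 0.0]}, index=["S1", "S2", "S3"])
    work = pd.DataFrame({"p": [0.0, 3.0]}, index=["S1", "S2"])
    expo = matrix_from(res, work)
    assert expo.exposed()["p"].to_dict() == {"S1": True, "S2": True, "S3": False}


# ---------------------------------------------------------------------------
# end-to-end recovery against generator truth


def test_end_to_end_matches_ground_truth():
    from scipy.stats import spearmanr

    cfg = default_config(seed=3)
    cfg.waves = [WaveSpec("wave1", 30, 30, (2000, 2005))]
    parcels = gen_landscape(cfg)
    apps = gen_applications(parcels, cfg)
    participants, addresses, truth_long = gen_cohort(parcels, apps, cfg)
    expo = build_exposure_matrix(apps, addresses, parcels, participants)

    truth = truth_long[truth_long["location"] == "residential"].pivot(
        index="participant_id", columns="pesticide", values="true_raw")
    computed = expo.raw["residential"]
    common = computed.index.intersection(truth.index)
    cols = [c for c in computed.columns if c in truth.columns]
    x = computed.loc[common, cols].to_numpy().ravel()
    y = truth.loc[common, cols].to_numpy().ravel()
    rho = spearmanr(x, y).statistic
    assert rho >= 0.95
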