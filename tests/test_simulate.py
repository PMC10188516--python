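"""Synthetic-data generators: determinism, structural constraints, and
agreement between recorded ground truth and generated artifacts."""

import numpy as np
import pandas as pd
import pytest

from pwastox.config import (ACRE_M2, CoappCluster, HillParams, PesticideSpec,
                            SimConfig, WaveSpec, default_config,
                            default_plate_truth)
from pwastox.simulate import (GroundTruth, gen_applications, gen_cohort,
                              gen_combo_plate, gen_landscape, gen_ocr,
                              gen_plate, simulate_cohort, simulate_exposures)
from pwastox.simulate.landscape import parcels_from_geojson, parcels_to_geojson


@pytest.fixture(scope="module")
def cfg():
    return default_config(seed=5)


@pytest.fixture(scope="module")
def parcels(cfg):
    return gen_landscape(cfg)


@pytest.fixture(scope="module")
def applications(cfg, parcels):
    return gen_applications(parcels, cfg)


# ---------------------------------------------------------------------------
# landscape


def test_landscape_shape_and_bounds(cfg, parcels):
    assert len(parcels) == cfg.n_parcels
    w, h = cfg.region_extent
    assert (parcels["x0"] >= 0).all() and (parcels["x1"] <= w).all()
    assert (parcels["y0"] >= 0).all() and (parcels["y1"] <= h).all()
    assert (parcels["x1"] > parcels["x0"]).all()
    assert parcels["parcel_id"].is_unique
    assert set(parcels["crop"]) <= set(cfg.crops)


def test_landscape_acres_consistent(parcels):
    area = (parcels["x1"] - parcels["x0"]) * (parcels["y1"] - parcels["y0"])
    assert np.allclose(parcels["acres"], area / ACRE_M2, rtol=1e-12)


def test_landscape_no_overlap(parcels):
    # jittered-grid layout: parcels live in disjoint cells
    boxes = parcels[["x0", "y0", "x1", "y1"]].to_numpy()
    for i in range(0, len(boxes), 17):
        a = boxes[i]
        others = np.delete(boxes, i, axis=0)
        overlap = ((others[:, 0] < a[2]) & (others[:, 2] > a[0])
                   & (others[:, 1] < a[3]) & (others[:, 3] > a[1]))
        assert not overlap.any()


def test_landscape_deterministic(cfg):
    again = gen_landscape(default_config(seed=5))
    pd.testing.assert_frame_equal(gen_landscape(cfg), again)
    different = gen_landscape(default_config(seed=6))
    assert not different.equals(gen_landscape(cfg))


def test_landscape_too_small_raises():
    with pytest.raises(ValueError, match="too small"):
        gen_landscape(SimConfig(n_parcels=10000, region_extent=(1000.0, 1000.0)))


def test_geojson_round_trip(parcels):
    back = parcels_from_geojson(parcels_to_geojson(parcels))
    pd.testing.assert_frame_equal(
        back[["parcel_id", "x0", "y0", "x1", "y1", "acres", "crop"]],
        parcels[["parcel_id", "x0", "y0", "x1", "y1", "acres", "crop"]],
        check_exact=False)


# ---------------------------------------------------------------------------
# applications


def test_applications_structure(cfg, applications):
    assert list(applications.columns) == ["year", "parcel_id", "pesticide",
                                          "pounds", "acres_treated", "crop"]
    assert (applications["pounds"] > 0).all()
    assert (applications["acres_treated"] > 0).all()
    y0, y1 = cfg.years
    assert applications["year"].between(y0, y1).all()


def test_applications_crop_restriction(cfg, parcels, applications):
    cotton_parcels = set(parcels.loc[parcels["crop"] == "cotton", "parcel_id"])
    for p in cfg.pesticides:
        if p.crop == "cotton":
            recs = applications[applications["pesticide"] == p.pid]
            assert not recs.empty
            assert set(recs["parcel_id"]) <= cotton_parcels


def test_applications_treated_acres_within_parcel(parcels, applications):
    acres = parcels.set_index("parcel_id")["acres"]
    assert (applications["acres_treated"]
            <= applications["parcel_id"].map(acres) + 1e-9).all()


def test_applications_cluster_cooccurrence(cfg, applications):
    # cluster members share parcel-years far more often than chance
    def years_set(pid):
        recs = applications[applications["pesticide"] == pid]
        return set(zip(recs["parcel_id"], recs["year"]))

    a, b = "insecticide_00", "insecticide_01"   # same cluster, rho = 0.8
    sa, sb = years_set(a), years_set(b)
    jaccard_cluster = len(sa & sb) / len(sa | sb)
    c = "herbicide_00"                          # independent singleton
    sc = years_set(c)
    jaccard_indep = len(sa & sc) / len(sa | sc)
    assert jaccard_cluster > 0.5
    assert jaccard_indep < 0.25


def test_applications_unknown_cluster_member_rejected():
    pest = [PesticideSpec("a")]
    with pytest.raises(ValueError, match="ghost"):
        SimConfig(pesticides=pest,
                  coapplication_clusters=[CoappCluster(("a", "ghost"))])


# ---------------------------------------------------------------------------
# statistical exposure route


def test_simulate_exposures_prevalence_and_skew(cfg):
    rng = np.random.default_rng(0)
    raw = simulate_exposures(cfg, 5000, rng)
    prev = (raw > 0).mean()
    assert np.allclose(prev, cfg.exposure_prevalence, atol=0.05)
    nonzero = raw.to_numpy()[raw.to_numpy() > 0]
    assert np.mean(nonzero) > np.median(nonzero)  # right-skewed


def test_simulate_exposures_cluster_correlation(cfg):
    rng = np.random.default_rng(1)
    raw = np.log1p(simulate_exposures(cfg, 3000, rng))
    r = raw.corr()
    assert r.at["insecticide_00", "insecticide_01"] > 0.5
    assert abs(r.at["insecticide_00", "herbicide_00"]) < 0.15


def test_simulate_cohort_quotas_and_determinism():
    cfg = default_config(seed=13)
    cfg.waves = [WaveSpec("wave1", 60, 40, (2000, 2007)),
                 WaveSpec("wave2", 30, 50, (2009, 2015))]
    participants, raw, z = simulate_cohort(cfg)
    counts = participants.groupby(["wave", "case"]).size()
    assert counts[("wave1", 1)] == 60 and counts[("wave1", 0)] == 40
    assert counts[("wave2", 1)] == 30 and counts[("wave2", 0)] == 50
    assert participants["participant_id"].is_unique
    assert list(raw.index) == list(participants["participant_id"])
    p2, r2, _ = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(participants, p2)
    pd.testing.assert_frame_equal(raw, r2)


def test_simulate_cohort_effect_enriches_cases():
    cfg = default_config(seed=29)
    cfg.causal_effects = {"insecticide_00": 1.5}
    cfg.waves = [WaveSpec("wave1", 300, 300, (2000, 2007))]
    participants, raw, _ = simulate_cohort(cfg)
    exposed = (raw["insecticide_00"] > 0).to_numpy()
    case = participants["case"].to_numpy() == 1
    assert exposed[case].mean() > exposed[~case].mean() + 0.05


# ---------------------------------------------------------------------------
# geospatial cohort route


def test_gen_cohort_contract(cfg, parcels, applications):
    cfg2 = default_config(seed=5)
    cfg2.waves = [WaveSpec("wave1", 25, 25, (2000, 2005))]
    participants, addresses, truth = gen_cohort(parcels, applications, cfg2)
    assert len(participants) == 50
    assert set(participants.columns) == {"participant_id", "wave", "case",
                                         "index_year", "age", "gender", "smoker"}
    # every participant has residential address history covering the window
    res = addresses[addresses["location"] == "residential"]
    spans = res.groupby("participant_id").agg(lo=("start_year", "min"),
                                              hi=("end_year", "max"))
    idx = participants.set_index("participant_id")["index_year"]
    assert (spans["lo"] == 1974).all()
    assert (spans["hi"] >= idx.loc[spans.index] - 10).all()
    assert {"participant_id", "location", "pesticide", "true_raw"} \
        <= set(truth.columns)


# ---------------------------------------------------------------------------
# plates


def test_plate_counts_follow_hill(cfg):
    meta, _, tc = gen_plate(cfg, with_objects=False)
    day11 = tc[tc["timepoint"] == "day11"].merge(meta, on="well_id")
    dmso = day11.loc[day11["role"] == "DMSO", "n_bright"]
    assert dmso.mean() == pytest.approx(100.0, abs=15.0)
    pos = day11.loc[day11["role"] == "positive", "n_bright"]
    assert pos.mean() < 25
    # a truly toxic compound collapses at the top dose; a flat one does not
    toxic = day11[(day11["compound"] == "defoliant_00") & (day11["dose"] == 30.0)]
    flat = day11[(day11["compound"] == "defoliant_01") & (day11["dose"] == 30.0)]
    assert toxic["n_bright"].mean() < 60
    assert flat["n_bright"].mean() > 70


def test_plate_baseline_counts_uniform(cfg):
    meta, _, tc = gen_plate(cfg, with_objects=False)
    base = tc[tc["timepoint"] == "baseline"].merge(meta, on="well_id")
    treated = base[base["role"] == "treated"]
    assert treated["n_bright"].mean() == pytest.approx(100.0, abs=10.0)


def test_plate_objects_encode_true_counts():
    cfg = default_config(seed=31)
    cfg.plate_truth = {k: cfg.plate_truth[k]
                       for k in list(cfg.plate_truth)[:4]}  # keep it small
    meta, objects, tc = gen_plate(cfg, with_objects=True)
    day11 = tc[tc["timepoint"] == "day11"].set_index("well_id")["n_bright"]
    # the bright population sits far above the dim background, so a midpoint
    # cut recovers the generator's reporter-positive count exactly
    bright = objects[objects["intensity"] > 10000].groupby("well_id").size()
    for wid in day11.index[:30]:
        assert bright.get(wid, 0) == day11[wid]


def test_combo_plate_structure():
    cfg = default_config(seed=3)
    compounds = ["defoliant_00", "herbicide_cotton", "insecticide_00"]
    wells = gen_combo_plate(cfg, compounds, dose=10.0, n_replicates=4)
    assert wells["condition"].nunique() == 2 ** 3
    assert (wells.groupby("condition").size() == 4).all()
    assert "DMSO" in set(wells["condition"])
    assert "defoliant_00+herbicide_cotton+insecticide_00" in set(wells["condition"])
    with pytest.raises(KeyError):
        gen_combo_plate(cfg, ["nope"])


def test_combo_plate_interaction_multiplier():
    truth = {"a": HillParams(100, 100, 10), "b": HillParams(100, 100, 10)}
    cfg = SimConfig(plate_truth=truth, seed=2, well_noise_sd=1e-6,
                    interaction_multipliers={frozenset({"a", "b"}): 0.5})
    wells = gen_combo_plate(cfg, ["a", "b"], dose=10.0, n_replicates=8)
    means = wells.groupby("condition")["count"].mean()
    # flat singletons stay at the control level; the pair is halved
    assert means["a"] == pytest.approx(100.0, abs=12.0)
    assert means["a+b"] == pytest.approx(50.0, abs=10.0)


# ---------------------------------------------------------------------------
# OCR traces and ground truth


def test_ocr_noiseless_levels(cfg):
    traces = gen_ocr(cfg)
    t = cfg.ocr_truth
    assert traces["trace_id"].nunique() == cfg.n_ocr_traces
    one = traces[traces["trace_id"] == "T00"]
    assert len(one) == 12
    by_seg = one.groupby("segment")["ocr"].unique()
    assert by_seg["basal"].tolist() == [t.non_mito + t.basal]
    assert by_seg["rot_aa"].tolist() == [t.non_mito]
    assert by_seg["fccp"].tolist() == [t.non_mito + t.maximal]


def test_ground_truth_round_trip(tmp_path):
    gt = GroundTruth(seed=4, causal_log_or={"a": 0.4},
                     coapplication_clusters=[["a", "b"]],
                     toxic_compounds=["a"],
                     combination_effects={"a|b": 0.5})
    path = tmp_path / "gt.json"
    gt.to_json(path)
    assert GroundTruth.from_json(path) == gt


def test_default_plate_truth_partition():
    truth, toxic = default_plate_truth(39, 10)
    assert len(truth) == 39 and len(toxic) == 10
    for name, hill in truth.items():
        if name in toxic:
            assert hill.response(30.0) < 50.0
        else:
            assert hill.response(30.0) == pytest.approx(100.0)
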