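"""End-to-end orchestration: simulate -> exposure -> PWAS -> ORA ->
co-exposure -> screen -> combos -> mito, with a run manifest.

Every stage communicates through documented CSV/GeoJSON files in the run
directory (see docs/data_dictionary.md), so stages can be re-run
independently and runs with the same configuration and seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import ora, run_pwas
from .coexposure import build_network, cluster, corr_matrix, crop_share_table
from .config import SimConfig, config_digest, default_config
from .exposure import BufferSpec, build_exposure_matrix
from .neurotox import (combo_analysis, count_positives, dose_summary,
                       mito_stress_table, toxicity_call, zprime)
from .simulate import (GroundTruth, gen_applications, gen_cohort,
                       gen_combo_plate, gen_ocr, gen_landscape, gen_plate)
from .simulate.landscape import parcels_to_geojson

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Pipeline-level knobs (thresholds mirror the study defaults)."""

    outdir: Path = Path("run")
    buffer: BufferSpec = field(default_factory=BufferSpec)
    window_start: int = 1974
    window_offset: int = 10
    min_exposed: int = 25
    fdr_tiers: tuple[float, float, float] = (0.01, 0.05, 0.10)
    assoc_fdr: float = 0.05
    corr_threshold: float = 0.45
    cluster_height: float = 0.55
    sd_mult: float = 3.0
    screen_dose: float = 30.0
    combo_dose: float = 10.0
    combo_size: int = 6

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if not (0 < self.corr_threshold <= 1 and 0 < self.cluster_height <= 2):
            raise ValueError("thresholds out of range")


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)
    return len(df)


def stage_simulate(cfg: SimConfig, out: Path) -> dict[str, int]:
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    parcels = gen_landscape(cfg)
    with open(out / "parcels.geojson", "w") as fh:
        json.dump(parcels_to_geojson(parcels), fh)
    counts["parcels"] = len(parcels)
    apps = gen_applications(parcels, cfg)
    counts["applications"] = _write(apps, out / "applications.csv")
    participants, addresses, truth_long = gen_cohort(parcels, apps, cfg)
    counts["participants"] = _write(participants, out / "participants.csv")
    counts["addresses"] = _write(addresses, out / "addresses.csv")
    counts["true_exposure"] = _write(truth_long, out / "true_exposure.csv")
    annot = annotations_table(cfg)
    counts["annotations"] = _write(annot, out / "annotations.csv")
    wells, objects, true_counts = gen_plate(cfg, with_objects=True)
    counts["wells"] = _write(wells, out / "wells.csv")
    counts["objects"] = _write(objects, out / "objects.csv")
    counts["true_counts"] = _write(true_counts, out / "true_counts.csv")
    ocr = gen_ocr(cfg)
    counts["ocr"] = _write(ocr, out / "ocr.csv")
    truth = GroundTruth(
        seed=cfg.seed,
        causal_log_or=dict(cfg.causal_effects),
        covariate_effects=dict(cfg.covariate_effects),
        coapplication_clusters=[list(c.members) for c in cfg.coapplication_clusters],
        toxic_compounds=sorted(c for c, h in cfg.plate_truth.items()
                               if h.bottom < 0.5 * h.top),
        combination_effects={"|".join(sorted(k)): v
                             for k, v in cfg.interaction_multipliers.items()},
        ocr_truth={"non_mito": cfg.ocr_truth.non_mito, "basal": cfg.ocr_truth.basal,
                   "atp_linked": cfg.ocr_truth.atp_linked,
                   "maximal": cfg.ocr_truth.maximal,
                   "noise_sd": cfg.ocr_truth.noise_sd},
    )
    truth.to_json(out / "ground_truth.json")
    return counts


def annotations_table(cfg: SimConfig) -> pd.DataFrame:
    """Long pesticide-group annotation table (use types, chemical classes,
    toxicity flags) from the configured panel."""
    rows = []
    for p in cfg.pesticides:
        rows.append({"pesticide": p.pid, "group": f"use:{p.use_type}"})
        rows.append({"pesticide": p.pid, "group": f"class:{p.chemical_class}"})
        for t in p.toxicity:
            rows.append({"pesticide": p.pid, "group": f"tox:{t}"})
    return pd.DataFrame(rows)


def stage_exposure(run: RunConfig) -> dict[str, int]:
    out = run.outdir
    from .simulate.landscape import parcels_from_geojson
    with open(out / "parcels.geojson") as fh:
        parcels = parcels_from_geojson(json.load(fh))
    apps = pd.read_csv(out / "applications.csv")
    addresses = pd.read_csv(out / "addresses.csv")
    participants = pd.read_csv(out / "participants.csv")
    expo = build_exposure_matrix(apps, addresses, parcels, participants,
                                 run.buffer, run.window_start, run.window_offset)
    long = expo.long()
    counts = {
        "exposure_raw": _write(long[["participant_id", "location", "pesticide", "raw"]],
                               out / "exposure_raw.csv"),
        "exposure_z": _write(long[["participant_id", "location", "pesticide", "z"]],
                             out / "exposure_z.csv"),
    }
    mask = expo.inclusion_mask(run.min_exposed)
    mdf = pd.DataFrame({"pesticide": mask.index, "n_exposed": expo.exposed_counts(),
                        "included": mask.values})
    counts["inclusion_mask"] = _write(mdf, out / "inclusion_mask.csv")
    return counts


def _load_exposure(run: RunConfig):
    """Rebuild an ExposureMatrix view from the stage CSV contracts."""
    from .exposure import ExposureMatrix
    out = run.outdir
    long_raw = pd.read_csv(out / "exposure_raw.csv")
    long_z = pd.read_csv(out / "exposure_z.csv")
    participants = pd.read_csv(out / "participants.csv")
    raw, z = {}, {}
    for loc, sub in long_raw.groupby("location"):
        raw[loc] = sub.pivot(index="participant_id", columns="pesticide", values="raw")
    for loc, sub in long_z.groupby("location"):
        z[loc] = sub.pivot(index="participant_id", columns="pesticide", values="z")
    pests = sorted(long_raw["pesticide"].unique())
    return ExposureMatrix(raw=raw, z=z, covered=pd.DataFrame(),
                          participants=participants, pesticides=pests), participants


def stage_pwas(run: RunConfig) -> dict[str, int]:
    expo, participants = _load_exposure(run)
    res = run_pwas(expo, participants, run.min_exposed, run.fdr_tiers)
    return {"pwas_results": _write(res, run.outdir / "pwas_results.csv")}


def stage_ora(run: RunConfig) -> dict[str, int]:
    out = run.outdir
    res = pd.read_csv(out / "pwas_results.csv")
    annotations = pd.read_csv(out / "annotations.csv")
    associated = set(res.loc[res["q"] <= run.assoc_fdr, "pesticide"])
    universe = set(res["pesticide"])
    tab = ora(associated, annotations, universe)
    return {"ora_results": _write(tab, out / "ora_results.csv")}


def stage_coexposure(run: RunConfig, toxic: set | None = None) -> dict[str, int]:
    out = run.outdir
    res = pd.read_csv(out / "pwas_results.csv")
    implicated = res.loc[res["implicated"], "pesticide"].tolist()
    expo, _ = _load_exposure(run)
    counts = {}
    if len(implicated) < 2:
        log.warning("fewer than two implicated pesticides; co-exposure skipped")
        return counts
    z_res = expo.z.get("residential")
    corr = corr_matrix(z_res, implicated)
    counts["corr_matrix"] = _write(corr.reset_index(), out / "corr_matrix.csv")
    if toxic is None and (out / "toxicity_calls.csv").exists():
        calls = pd.read_csv(out / "toxicity_calls.csv")
        toxic = set(calls.loc[calls["toxic"], "compound"])
    toxic = set(toxic or set()) & set(corr.index)
    if toxic:
        fdr = res.set_index("pesticide")["q"].to_dict()
        g, nodes, summary = build_network(corr, toxic, run.corr_threshold, fdr)
        edges = pd.DataFrame(
            [{"source": u, "target": v, "r": d["weight"]}
             for u, v, d in g.edges(data=True)]
        ).sort_values(["source", "target"], kind="stable") if g.number_of_edges() \
            else pd.DataFrame(columns=["source", "target", "r"])
        counts["edges"] = _write(edges, out / "edges.csv")
        counts["network_nodes"] = _write(nodes, out / "network_nodes.csv")
        with open(out / "network_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
    complete = corr.dropna(axis=0, how="any").index
    part = cluster(corr.loc[complete, complete], run.cluster_height)
    counts["clusters"] = _write(part.rename_axis("pesticide").reset_index(),
                                out / "clusters.csv")
    apps = pd.read_csv(out / "applications.csv")
    counts["crop_share"] = _write(crop_share_table(apps, "cotton"),
                                  out / "crop_share.csv")
    return counts


def stage_screen(run: RunConfig) -> dict[str, int]:
    out = run.outdir
    wells = pd.read_csv(out / "wells.csv")
    objects = pd.read_csv(out / "objects.csv")  # day-11 imaging objects
    wc = count_positives(objects, wells)
    counts = {"well_counts": _write(wc, out / "well_counts.csv")}
    calls = toxicity_call(wc, timepoint=None, sd_mult=run.sd_mult,
                          dose=run.screen_dose)
    counts["toxicity_calls"] = _write(calls, out / "toxicity_calls.csv")
    zp = zprime(wc.loc[wc["role"] == "DMSO", "count"],
                wc.loc[wc["role"] == "positive", "count"])
    (out / "zprime.txt").write_text(f"{zp:.4f}\n")
    summaries = []
    for compound in sorted(calls.loc[calls["toxic"], "compound"]):
        ds = dose_summary(wc, compound, timepoint=None)
        ds.insert(0, "compound", compound)
        ds["ld50"] = ds.attrs["ld50"]
        summaries.append(ds)
    if summaries:
        counts["dose_summary"] = _write(pd.concat(summaries, ignore_index=True),
                                        out / "dose_summary.csv")
    return counts


def stage_combos(run: RunConfig, cfg: SimConfig) -> dict[str, int]:
    out = run.outdir
    compounds = _combo_panel(run, cfg)
    wells = gen_combo_plate(cfg, compounds, dose=run.combo_dose)
    conditions, tests = combo_analysis(wells, compounds)
    counts = {"combos": _write(conditions, out / "combos.csv"),
              "combo_tests": _write(tests, out / "combo_tests.csv")}
    return counts


def _combo_panel(run: RunConfig, cfg: SimConfig) -> list[str]:
    """Pick the co-exposure panel: the largest cluster with screen truth
    (the cotton cluster in the default configuration), topped up as needed."""
    want = run.combo_size
    pool: list[str] = []
    cl_path = run.outdir / "clusters.csv"
    if cl_path.exists():
        cl = pd.read_csv(cl_path)
        for _, grp in sorted(cl.groupby("cluster"), key=lambda kv: -len(kv[1])):
            pool = [p for p in grp["pesticide"] if p in cfg.plate_truth]
            if pool:
                break
    for c in sorted(cfg.plate_truth):
        if len(pool) >= want:
            break
        if c not in pool:
            pool.append(c)
    return sorted(pool[:want])


def stage_mito(run: RunConfig) -> dict[str, int]:
    out = run.outdir
    traces = pd.read_csv(out / "ocr.csv")
    params = mito_stress_table(traces)
    return {"mito_params": _write(params, out / "mito_params.csv")}


def run_all(cfg: SimConfig | None = None, run: RunConfig | None = None) -> dict:
    """Run every stage in dependency order; returns the manifest."""
    cfg = cfg if cfg is not None else default_config()
    run = run if run is not None else RunConfig()
    out = run.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg.seed,
                "config_digest": config_digest(cfg), "rows": {}}
    stages = [
        ("simulate", lambda: stage_simulate(cfg, out)),
        ("exposure", lambda: stage_exposure(run)),
        ("pwas", lambda: stage_pwas(run)),
        ("ora", lambda: stage_ora(run)),
        ("screen", lambda: stage_screen(run)),
        ("coexposure", lambda: stage_coexposure(run)),
        ("combos", lambda: stage_combos(run, cfg)),
        ("mito", lambda: stage_mito(run)),
    ]
    for name, fn in stages:
        try:
            counts = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["rows"].update(counts)
        log.info("stage %s done: %s", name, counts)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
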