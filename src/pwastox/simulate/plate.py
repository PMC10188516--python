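"""High-content screen plate generator.

Well counts follow each compound's Hill dose-response times lognormal
well-to-well noise.  Object tables carry a two-population intensity mixture
(a dominant dim background/debris population and a sparse bright
reporter-positive population) plus deliberately out-of-gate junk objects, so
the object-filtering and control-referenced intensity-threshold steps are
exercised end to end.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ..config import SimConfig

N_FIELDS = 4
DMSO_TOP = 100.0      # mean reporter-positive count in an untreated well
POSITIVE_MEAN = 12.0  # rotenone-like positive control


def _draw_count(mean: float, rng, noise_sd: float) -> int:
    return int(rng.poisson(mean * np.exp(rng.normal(0.0, noise_sd))))


def gen_plate(config: SimConfig, with_objects: bool = True,
              timepoints: tuple[str, ...] = ("baseline", "day11")):
    """Generate (wells, objects, true_counts).

    ``wells`` has one row per well and timepoint; ``true_counts`` records the
    generator's reporter-positive count per well (the screen's ground truth).
    ``objects`` is None when ``with_objects`` is False.
    """
    rng = config.rng("plate")
    wrows = []
    n_wells = 0

    def add_well(compound, dose, role, rep):
        nonlocal n_wells
        n_wells += 1
        wid = f"W{n_wells:04d}"
        for tp in timepoints:
            if tp == "baseline":
                mean = DMSO_TOP
            elif role == "positive":
                mean = POSITIVE_MEAN
            elif role in ("DMSO", "water"):
                mean = DMSO_TOP
            else:
                if dose < 0:
                    raise ValueError("dose must be non-negative")
                hill = config.plate_truth[compound]
                mean = DMSO_TOP * hill.response(dose) / hill.top
            wrows.append({"well_id": wid, "compound": compound, "dose": dose,
                          "role": role, "replicate": rep, "timepoint": tp,
                          "n_bright": _draw_count(mean, rng, config.well_noise_sd)})

    for rep in range(config.n_dmso_wells):
        add_well("DMSO", 0.0, "DMSO", rep)
    for rep in range(max(config.n_dmso_wells // 2, 2)):
        add_well("water", 0.0, "water", rep)
    for rep in range(config.n_positive_wells):
        add_well("rotenone", 0.0, "positive", rep)
    for compound in sorted(config.plate_truth):
        for dose in config.doses:
            for rep in range(config.n_replicates):
                add_well(compound, float(dose), "treated", rep)

    wells = pd.DataFrame(wrows)
    true_counts = wells[["well_id", "timepoint", "n_bright"]].copy()
    meta = (wells.drop(columns=["n_bright", "timepoint"])
            .drop_duplicates("well_id").reset_index(drop=True))

    objects = None
    if with_objects:
        objects = _gen_objects(wells, config, rng)
    return meta, objects, true_counts


def _gen_objects(wells: pd.DataFrame, config: SimConfig, rng) -> pd.DataFrame:
    day11 = wells[wells["timepoint"] == "day11"]
    dim_mu, dim_sd = config.dim_intensity
    bri_mu, bri_sd = config.bright_intensity
    frames = []
    for _, w in day11.iterrows():
        n_bright = int(w["n_bright"])
        n_dim = int(rng.poisson(config.dim_per_well))
        n_junk = int(rng.poisson(40))
        n = n_bright + n_dim + n_junk
        area = np.empty(n)
        roundness = np.empty(n)
        intensity = np.empty(n)
        # in-gate objects: area in (40, 400), roundness > 0.7
        k = n_bright + n_dim
        area[:k] = rng.uniform(60.0, 350.0, k)
        roundness[:k] = rng.uniform(0.75, 1.0, k)
        intensity[:n_bright] = rng.normal(bri_mu, bri_sd, n_bright)
        intensity[n_bright:k] = rng.normal(dim_mu, dim_sd, n_dim)
        # junk: fails exactly one gate each (size, shape, or brightness)
        which = rng.integers(0, 3, n_junk)
        area[k:] = np.where(which == 0, rng.uniform(5.0, 39.0, n_junk),
                            rng.uniform(60.0, 350.0, n_junk))
        roundness[k:] = np.where(which == 1, rng.uniform(0.1, 0.65, n_junk),
                                 rng.uniform(0.75, 1.0, n_junk))
        intensity[k:] = np.where(which == 2, rng.uniform(50.0, 450.0, n_junk),
                                 rng.normal(dim_mu, dim_sd, n_junk))
        frames.append(pd.DataFrame({
            "well_id": w["well_id"],
            "field": rng.integers(1, N_FIELDS + 1, n),
            "area": np.abs(area),
            "roundness": np.clip(roundness, 0.0, 1.0),
            "intensity": np.maximum(intensity, 1.0),
        }))
    return pd.concat(frames, ignore_index=True)


def gen_combo_plate(config: SimConfig, compounds: list[str], dose: float = 10.0,
                    n_replicates: int = 4):
    """All-combinations co-exposure plate for ``compounds`` (2^k conditions
    including DMSO), under multiplicative-independence survival modified by
    any configured pairwise interaction multipliers.

    Returns a well table with columns condition, replicate, count; the
    condition label is '+'-joined sorted compound names, 'DMSO' for the
    empty set.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    for c in compounds:
        if c not in config.plate_truth:
            raise KeyError(f"no Hill truth configured for compound {c!r}")
    rng = config.rng("combo")
    surv = {c: config.plate_truth[c].response(dose) / config.plate_truth[c].top
            for c in compounds}
    rows = []
    for r in range(len(compounds) + 1):
        for subset in itertools.combinations(sorted(compounds), r):
            s = 1.0
            for c in subset:
                s *= surv[c]
            for a, b in itertools.combinations(subset, 2):
                s *= config.interaction_multipliers.get(frozenset({a, b}), 1.0)
            label = "+".join(subset) if subset else "DMSO"
            for rep in range(n_replicates):
                rows.append({"condition": label, "replicate": rep,
                             "count": _draw_count(DMSO_TOP * s, rng, config.well_noise_sd)})
    return pd.DataFrame(rows)
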