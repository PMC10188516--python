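"""Application-record generator emulating a pesticide-use-report structure:
year, parcel, pesticide, pounds applied, acres treated, crop.

Pesticides sharing a co-application cluster are applied to the same
parcel-years with the configured probability: each cluster draws one shared
parcel-year indicator, and each member either copies it (with probability
equal to the cluster correlation) or draws independently.  A correlation of
1.0 therefore yields identical application sets.  Crop-restricted pesticides
(the simulated defoliants) only ever appear on parcels growing their crop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimConfig


def gen_applications(parcels: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    if parcels.empty:
        raise ValueError("no parcels to apply pesticides to")
    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    rng = config.rng("applications")

    n_parcels, n_years = len(parcels), len(years)
    crop = parcels["crop"].to_numpy()
    acres = parcels["acres"].to_numpy()
    pid_arr = parcels["parcel_id"].to_numpy()

    clustered = {m for cl in config.coapplication_clusters for m in cl.members}
    groups: list[tuple[tuple[str, ...], float]] = [
        (cl.members, cl.correlation) for cl in config.coapplication_clusters
    ]
    groups += [((p.pid,), 0.0) for p in config.pesticides if p.pid not in clustered]

    spec_by_id = {p.pid: p for p in config.pesticides}
    frames = []
    for members, corr in groups:
        shared = rng.random((n_parcels, n_years)) < config.app_prob
        for pid in members:
            if pid not in spec_by_id:
                raise KeyError(f"pesticide {pid!r} absent from config")
            spec = spec_by_id[pid]
            own = rng.random((n_parcels, n_years)) < config.app_prob
            copy = rng.random((n_parcels, n_years)) < corr
            applied = np.where(copy, shared, own)
            if spec.crop is not None:
                applied &= (crop == spec.crop)[:, None]
            pi, yi = np.nonzero(applied)
            if pi.size == 0:
                continue
            pounds = rng.lognormal(config.log_pounds_mean, config.log_pounds_sd, pi.size)
            treated = rng.uniform(0.2, 1.0, pi.size) * acres[pi]
            frames.append(pd.DataFrame({
                "year": years[yi],
                "parcel_id": pid_arr[pi],
                "pesticide": pid,
                "pounds": pounds,
                "acres_treated": treated,
                "crop": crop[pi],
            }))
    if not frames:
        return pd.DataFrame(
            columns=["year", "parcel_id", "pesticide", "pounds", "acres_treated", "crop"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["year", "parcel_id", "pesticide"], kind="stable").reset_index(drop=True)
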