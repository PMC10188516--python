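"""Case-control cohort generators.

Two routes share the same causal model (a logistic outcome whose linear
predictor uses true standardized exposures):

* :func:`gen_cohort` -- the geospatial route.  Participants receive address
  spells inside the simulated landscape; their true exposures are computed
  from the application records via the closed-form circle-rectangle overlap
  (an independent code path from the shapely-based pipeline), and case status
  is rejection-sampled until per-wave quotas are met.

* :func:`simulate_cohort` -- the statistical route.  Raw exposures are drawn
  directly from a cluster-correlated lognormal hurdle model, which makes
  replicate-heavy calibration studies (null FDR control, CI coverage, cluster
  recovery) cheap.  It emulates the participant-level joint distribution the
  geospatial route induces: right-skewed intensities, a point mass at zero,
  and within-cluster co-exposure correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ..config import SimConfig
from ..geometry import circle_rect_overlap

WINDOW_START = 1974
WINDOW_OFFSET = 10
DEFAULT_RADIUS = 500.0


# ---------------------------------------------------------------------------
# statistical route


def simulate_exposures(config: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw an n x p matrix of raw windowed exposure summaries (lbs/acre).

    Latent factor model: pesticides in a co-application cluster share a
    Gaussian factor with loading sqrt(rho); a participant is exposed when the
    latent value exceeds the (1 - prevalence) quantile, with a lognormal
    intensity given exposure.
    """
    pids = config.pesticide_ids
    p = len(pids)
    latent = np.empty((n, p))
    eps = rng.standard_normal((n, p))
    factors = rng.standard_normal((n, max(len(config.coapplication_clusters), 1)))
    for j, pid in enumerate(pids):
        g = config.cluster_of(pid)
        if g is None:
            latent[:, j] = eps[:, j]
        else:
            rho = config.coapplication_clusters[g].correlation
            latent[:, j] = np.sqrt(rho) * factors[:, g] + np.sqrt(1.0 - rho) * eps[:, j]
    thresh = norm.ppf(1.0 - config.exposure_prevalence)
    raw = np.where(
        latent > thresh,
        np.exp(config.log_intensity_mean + config.log_intensity_sd * latent),
        0.0,
    )
    return pd.DataFrame(raw, columns=pids)


def _standardize(raw: pd.DataFrame, mu=None, sd=None):
    logged = np.log1p(raw)
    if mu is None:
        mu = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=1)
    z = (logged - mu) / sd.replace(0.0, np.nan)
    return z, mu, sd


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame({
        "age": np.clip(rng.normal(65.0, 8.0, n), 40.0, 90.0).round(1),
        "gender": rng.choice(["M", "F"], n),
        "smoker": rng.integers(0, 2, n),
    })


def _covariate_eta(cov: pd.DataFrame, effects: dict) -> np.ndarray:
    """Centered covariate contribution to the linear predictor."""
    eta = np.zeros(len(cov))
    for name, beta in effects.items():
        if name == "gender_male":
            eta += beta * ((cov["gender"] == "M").to_numpy(float) - 0.5)
        elif name == "smoker":
            eta += beta * (cov["smoker"].to_numpy(float) - 0.5)
        elif name == "age_per_decade":
            eta += beta * (cov["age"].to_numpy(float) - 65.0) / 10.0
        else:
            raise KeyError(f"unknown covariate effect {name!r}")
    return eta


def simulate_cohort(config: SimConfig, gender_effects: dict[str, float] | None = None):
    """Statistical-route cohort: returns (participants, raw_exposures, z_exposures).

    ``raw_exposures``/``z_exposures`` are wide (participant x pesticide)
    residential-layer frames; z is standardized within wave.  Case status is
    rejection-sampled from the logistic model until per-wave quotas are met.
    ``gender_effects`` optionally maps pesticide -> extra log-OR applied to
    men only (to plant exposure-by-gender interactions).
    """
    rng = config.rng("cohort")
    parts, raws, zs = [], [], []
    counter = 0
    for wave in config.waves:
        need_ca, need_co = wave.n_cases, wave.n_controls
        if need_ca + need_co == 0:
            raise ValueError(f"wave {wave.name} has zero participants requested")
        got_ca = got_co = 0
        mu = sd = None
        rows_p, rows_raw, rows_z = [], [], []
        for _ in range(60):
            if got_ca >= need_ca and got_co >= need_co:
                break
            batch = int(2.6 * (need_ca + need_co - got_ca - got_co)) + 50
            raw = simulate_exposures(config, batch, rng)
            z, mu, sd = _standardize(raw, mu, sd)
            cov = _covariates(batch, rng)
            eta = _covariate_eta(cov, config.covariate_effects)
            for pid, beta in config.causal_effects.items():
                eta += beta * z[pid].fillna(0.0).to_numpy()
            if gender_effects:
                male = (cov["gender"] == "M").to_numpy(float)
                for pid, beta in gender_effects.items():
                    eta += beta * male * z[pid].fillna(0.0).to_numpy()
            case = rng.random(batch) < expit(eta)
            for is_case in (True, False):
                need = (need_ca - got_ca) if is_case else (need_co - got_co)
                idx = np.nonzero(case == is_case)[0][:max(need, 0)]
                for i in idx:
                    rows_p.append({
                        "participant_id": f"S{counter:05d}",
                        "wave": wave.name,
                        "case": int(is_case),
                        "index_year": int(rng.integers(wave.index_years[0],
                                                       wave.index_years[1] + 1)),
                        **cov.iloc[i].to_dict(),
                    })
                    rows_raw.append(raw.iloc[i])
                    rows_z.append(z.iloc[i])
                    counter += 1
                if is_case:
                    got_ca += len(idx)
                else:
                    got_co += len(idx)
        if got_ca < need_ca or got_co < need_co:
            raise RuntimeError(f"could not fill case/control quotas for {wave.name}")
        parts.append(pd.DataFrame(rows_p))
        raws.append(pd.DataFrame(rows_raw).reset_index(drop=True))
        zs.append(pd.DataFrame(rows_z).reset_index(drop=True))
    participants = pd.concat(parts, ignore_index=True)
    raw_all = pd.concat(raws, ignore_index=True)
    z_all = pd.concat(zs, ignore_index=True)
    raw_all.index = participants["participant_id"]
    z_all.index = participants["participant_id"]
    return participants, raw_all, z_all


def exposure_matrix_from_cohort(participants: pd.DataFrame, raw: pd.DataFrame,
                                location: str = "residential"):
    """Wrap a statistical-route cohort as a single-layer ExposureMatrix,
    standardizing within wave exactly as the pipeline does."""
    from ..exposure import ExposureMatrix, transform

    wave = participants.set_index("participant_id")["wave"]
    zs = []
    for _, sub in raw.groupby(raw.index.map(wave)):
        zs.append(pd.DataFrame({c: transform(sub[c], strict=False) for c in raw.columns},
                               index=sub.index))
    z = pd.concat(zs).reindex(raw.index)
    return ExposureMatrix(raw={location: raw}, z={location: z},
                          covered=pd.DataFrame(), participants=participants,
                          pesticides=list(raw.columns))


# ---------------------------------------------------------------------------
# geospatial route


def _spells(rng, start: int, end: int, max_spells: int) -> list[tuple[int, int]]:
    """Partition [start, end] into 1..max_spells whole-year spells."""
    k = int(rng.integers(1, max_spells + 1))
    if k == 1 or end - start < k:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(start + 1, end + 1), size=k - 1, replace=False))
    bounds = [start, *cuts.tolist(), end + 1]
    return [(bounds[i], bounds[i + 1] - 1) for i in range(k)]


def _gen_addresses(config, wave, n, rng, id_offset):
    """Participants with residential (full coverage) and optional workplace spells."""
    width, height = config.region_extent
    prows, arows = [], []
    for i in range(n):
        pid = f"S{id_offset + i:05d}"
        index_year = int(rng.integers(wave.index_years[0], wave.index_years[1] + 1))
        prows.append({"participant_id": pid, "wave": wave.name,
                      "index_year": index_year})
        win_end = index_year - WINDOW_OFFSET
        for s, e in _spells(rng, WINDOW_START, index_year, 3):
            arows.append({"participant_id": pid, "location": "residential",
                          "x": rng.uniform(0, width), "y": rng.uniform(0, height),
                          "start_year": s, "end_year": e})
        if rng.random() < config.workplace_prob:
            # workplace histories may only partially cover the window
            w0 = int(rng.integers(WINDOW_START, max(win_end - 2, WINDOW_START) + 1))
            for s, e in _spells(rng, w0, index_year, 2):
                arows.append({"participant_id": pid, "location": "workplace",
                              "x": rng.uniform(0, width), "y": rng.uniform(0, height),
                              "start_year": s, "end_year": e})
    return pd.DataFrame(prows), pd.DataFrame(arows)


def true_exposure_summaries(addresses: pd.DataFrame, participants: pd.DataFrame,
                            applications: pd.DataFrame, parcels: pd.DataFrame,
                            radius: float = DEFAULT_RADIUS) -> pd.DataFrame:
    """Ground-truth windowed raw summaries via the analytic overlap formula.

    Long frame: participant_id, location, pesticide, true_raw.  Participants
    with no covered window years for a location are absent for that location.
    """
    from scipy.spatial import cKDTree

    px = (parcels["x0"].to_numpy() + parcels["x1"].to_numpy()) / 2
    py = (parcels["y0"].to_numpy() + parcels["y1"].to_numpy()) / 2
    half_diag = np.hypot(parcels["x1"] - parcels["x0"], parcels["y1"] - parcels["y0"]).max() / 2
    tree = cKDTree(np.column_stack([px, py]))

    addr = addresses.reset_index(drop=True).copy()
    addr["addr_idx"] = addr.index
    cand = tree.query_ball_point(addr[["x", "y"]].to_numpy(), r=radius + half_diag + 1.0)

    pairs = []
    parcel_arr = parcels.reset_index(drop=True)
    for ai, plist in enumerate(cand):
        if not plist:
            continue
        sub = parcel_arr.iloc[plist]
        inter = circle_rect_overlap(addr.at[ai, "x"], addr.at[ai, "y"], radius,
                                    sub["x0"].to_numpy(), sub["y0"].to_numpy(),
                                    sub["x1"].to_numpy(), sub["y1"].to_numpy())
        area = (sub["x1"] - sub["x0"]).to_numpy() * (sub["y1"] - sub["y0"]).to_numpy()
        frac = np.atleast_1d(inter) / area
        keep = frac > 0
        for pidx, f in zip(sub.index[keep], np.atleast_1d(frac)[keep]):
            pairs.append((ai, parcel_arr.at[pidx, "parcel_id"], f))
    frac_df = pd.DataFrame(pairs, columns=["addr_idx", "parcel_id", "frac"])

    apps = applications.copy()
    if (apps["acres_treated"] <= 0).any():
        raise ValueError("application records with non-positive treated acres")
    apps["intensity"] = apps["pounds"] / apps["acres_treated"]
    contrib = frac_df.merge(apps[["parcel_id", "year", "pesticide", "intensity"]],
                            on="parcel_id")
    contrib["value"] = contrib["intensity"] * contrib["frac"]
    vals = (contrib.groupby(["addr_idx", "year", "pesticide"])["value"]
            .sum().unstack(fill_value=0.0))

    # expand spells to covered years, clipped to each participant's window
    meta = participants.set_index("participant_id")["index_year"]
    grids = []
    for _, a in addr.iterrows():
        win_end = int(meta[a["participant_id"]]) - WINDOW_OFFSET
        lo = max(int(a["start_year"]), WINDOW_START)
        hi = min(int(a["end_year"]), win_end)
        if hi < lo:
            continue
        yrs = np.arange(lo, hi + 1)
        grids.append(pd.DataFrame({"participant_id": a["participant_id"],
                                   "location": a["location"],
                                   "addr_idx": a["addr_idx"], "year": yrs}))
    if not grids:
        return pd.DataFrame(columns=["participant_id", "location", "pesticide", "true_raw"])
    grid = pd.concat(grids, ignore_index=True)
    grid = grid.join(vals, on=["addr_idx", "year"])
    pest_cols = list(vals.columns)
    grid[pest_cols] = grid[pest_cols].fillna(0.0)
    summary = grid.groupby(["participant_id", "location"])[pest_cols].mean()
    out = summary.stack().rename("true_raw").reset_index()
    out.columns = ["participant_id", "location", "pesticide", "true_raw"]
    return out


def gen_cohort(parcels: pd.DataFrame, applications: pd.DataFrame, config: SimConfig,
               radius: float = DEFAULT_RADIUS):
    """Geospatial-route cohort: (participants, addresses, truth_long).

    Case status follows the logistic model on residential true standardized
    exposures (standardized within wave); quotas per wave are met by rejection
    sampling over candidate pools.
    """
    rng = config.rng("cohort")
    all_parts, all_addrs, all_truth = [], [], []
    counter = 0
    for wave in config.waves:
        need_ca, need_co = wave.n_cases, wave.n_controls
        if need_ca + need_co == 0:
            raise ValueError(f"wave {wave.name} has zero participants requested")
        pool_n = int(2.8 * (need_ca + need_co)) + 40
        sel_p, sel_a, sel_t = [], [], []
        got_ca = got_co = 0
        mu = sd = None
        for _ in range(12):
            if got_ca >= need_ca and got_co >= need_co:
                break
            parts, addrs = _gen_addresses(config, wave, pool_n, rng, counter)
            counter += pool_n
            cov = _covariates(pool_n, rng)
            parts = pd.concat([parts, cov], axis=1)
            truth = true_exposure_summaries(addrs, parts, applications, parcels, radius)
            res = (truth[truth["location"] == "residential"]
                   .pivot(index="participant_id", columns="pesticide", values="true_raw")
                   .reindex(parts["participant_id"]).fillna(0.0))
            for pid in config.pesticide_ids:
                if pid not in res.columns:
                    res[pid] = 0.0
            res = res[config.pesticide_ids]
            z, mu, sd = _standardize(res, mu, sd)
            eta = _covariate_eta(parts, config.covariate_effects)
            for pid, beta in config.causal_effects.items():
                eta += beta * z[pid].fillna(0.0).to_numpy()
            case = rng.random(pool_n) < expit(eta)
            parts["case"] = case.astype(int)
            for is_case in (True, False):
                need = (need_ca - got_ca) if is_case else (need_co - got_co)
                chosen = parts[parts["case"] == int(is_case)].head(max(need, 0))
                sel_p.append(chosen)
                sel_a.append(addrs[addrs["participant_id"].isin(chosen["participant_id"])])
                sel_t.append(truth[truth["participant_id"].isin(chosen["participant_id"])])
                if is_case:
                    got_ca += len(chosen)
                else:
                    got_co += len(chosen)
        if got_ca < need_ca or got_co < need_co:
            raise RuntimeError(f"could not fill case/control quotas for {wave.name}")
        all_parts.append(pd.concat(sel_p, ignore_index=True))
        all_addrs.append(pd.concat(sel_a, ignore_index=True))
        all_truth.append(pd.concat(sel_t, ignore_index=True))
    participants = pd.concat(all_parts, ignore_index=True)
    addresses = pd.concat(all_addrs, ignore_index=True)
    truth_long = pd.concat(all_truth, ignore_index=True)
    cols = ["participant_id", "wave", "case", "index_year", "age", "gender", "smoker"]
    return participants[cols], addresses.reset_index(drop=True), truth_long
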