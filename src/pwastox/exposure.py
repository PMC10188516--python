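"""Record-based GIS exposure assessment.

For each participant address we intersect a disc buffer (default 500 m) with
every parcel, weight each application's intensity (pounds divided by treated
acres) by the fraction of the parcel's area inside the buffer, and sum per
pesticide and calendar year.  Annual values are averaged over the exposure
window -- window start (1974) through ten years before each participant's
index year -- using only years covered by address history for that location
type.  Raw summaries are log1p-transformed, centered, and scaled to unit SD
within each wave-by-location stratum, so association estimates are odds
ratios per SD of transformed exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

QUAD_SEGS = 16  # disc approximated by a 64-gon
WINDOW_START = 1974
WINDOW_OFFSET = 10


@dataclass(frozen=True)
class BufferSpec:
    """Buffer radius around each address, in meters."""

    radius: float = 500.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("buffer radius must be > 0")


def buffer_fraction(address_xy, parcel_geom, spec: BufferSpec = BufferSpec()) -> float:
    """Fraction of the parcel's area inside the disc buffer around the address."""
    if parcel_geom.area <= 0:
        raise ValueError("parcel geometry has zero area")
    disc = Point(address_xy).buffer(spec.radius, quad_segs=QUAD_SEGS)
    return disc.intersection(parcel_geom).area / parcel_geom.area


def _parcel_geoms(parcels: pd.DataFrame):
    """Shapely polygons for a parcel table; accepts rectangle columns or a
    pre-built 'geometry' column."""
    if "geometry" in parcels.columns:
        return list(parcels["geometry"])
    from shapely.geometry import box
    return [box(p.x0, p.y0, p.x1, p.y1) for p in parcels.itertuples()]


def _address_parcel_fractions(addresses: pd.DataFrame, parcels: pd.DataFrame,
                              spec: BufferSpec) -> pd.DataFrame:
    """(addr_idx, parcel_id, frac) for all pairs with positive overlap."""
    geoms = _parcel_geoms(parcels)
    tree = STRtree(geoms)
    pids = parcels["parcel_id"].to_numpy()
    rows = []
    for ai, (x, y) in enumerate(zip(addresses["x"], addresses["y"])):
        disc = Point(x, y).buffer(spec.radius, quad_segs=QUAD_SEGS)
        for gi in tree.query(disc):
            geom = geoms[gi]
            if geom.area <= 0:
                raise ValueError(f"parcel {pids[gi]} has zero area")
            a = disc.intersection(geom).area
            if a > 0:
                rows.append((ai, pids[gi], a / geom.area))
    return pd.DataFrame(rows, columns=["addr_idx", "parcel_id", "frac"])


def _spell_year_weights(addresses: pd.DataFrame) -> pd.DataFrame:
    """Expand address spells to (participant, location, addr_idx, year, weight).

    Weights are months occupied in the year when start_month/end_month columns
    are present, otherwise 1 (equal weighting across same-year spells).
    """
    has_months = {"start_month", "end_month"}.issubset(addresses.columns)
    rows = []
    for a in addresses.itertuples():
        years = np.arange(int(a.start_year), int(a.end_year) + 1)
        if has_months:
            w = np.full(years.size, 12.0)
            w[0] -= float(a.start_month) - 1.0
            w[-1] -= 12.0 - float(a.end_month)
        else:
            w = np.ones(years.size)
        for y, wy in zip(years, w):
            rows.append((a.participant_id, a.location, a.Index, int(y), float(wy)))
    return pd.DataFrame(rows, columns=["participant_id", "location", "addr_idx",
                                       "year", "weight"])


def compute_annual_exposures(applications: pd.DataFrame, addresses: pd.DataFrame,
                             parcels: pd.DataFrame,
                             spec: BufferSpec = BufferSpec()) -> pd.DataFrame:
    """Annual lbs/acre per (participant, location, year, pesticide).

    Returns a frame indexed by (participant_id, location, year) with one
    column per pesticide; covered years with no applications are zero.
    Raises on application records with non-positive treated acres.
    """
    bad = applications[applications["acres_treated"] <= 0]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"application record with acres_treated <= 0: year={r['year']} "
            f"parcel={r['parcel_id']} pesticide={r['pesticide']}"
        )
    addresses = addresses.reset_index(drop=True)
    fracs = _address_parcel_fractions(addresses, parcels, spec)
    grid = _spell_year_weights(addresses)

    apps = applications.copy()
    apps["intensity"] = apps["pounds"] / apps["acres_treated"]
    if fracs.empty:
        vals = pd.DataFrame(index=pd.MultiIndex.from_arrays([[], []],
                                                            names=["addr_idx", "year"]))
    else:
        contrib = fracs.merge(apps[["parcel_id", "year", "pesticide", "intensity"]],
                              on="parcel_id")
        contrib["value"] = contrib["intensity"] * contrib["frac"]
        vals = (contrib.groupby(["addr_idx", "year", "pesticide"])["value"]
                .sum().unstack(fill_value=0.0))

    pest_cols = sorted(set(applications["pesticide"]))
    grid = grid.join(vals, on=["addr_idx", "year"])
    for c in pest_cols:
        if c not in grid.columns:
            grid[c] = 0.0
    grid[pest_cols] = grid[pest_cols].fillna(0.0)

    # duration-weighted mean across same-year spells of one location type
    wsum = grid.groupby(["participant_id", "location", "year"])["weight"].transform("sum")
    grid[pest_cols] = grid[pest_cols].mul(grid["weight"] / wsum, axis=0)
    annual = grid.groupby(["participant_id", "location", "year"])[pest_cols].sum()
    return annual


def annual_exposure(applications, addresses, parcels, year: int,
                    spec: BufferSpec = BufferSpec()) -> pd.DataFrame:
    """Annual lbs/acre rows for a single calendar year (long format)."""
    addresses = addresses[(addresses["start_year"] <= year)
                          & (addresses["end_year"] >= year)]
    if addresses.empty:
        return pd.DataFrame(columns=["participant_id", "location", "pesticide",
                                     "year", "lbs_per_acre"])
    annual = compute_annual_exposures(applications, addresses, parcels, spec)
    annual = annual.loc[annual.index.get_level_values("year") == year]
    out = annual.stack().rename("lbs_per_acre").reset_index()
    out.columns = ["participant_id", "location", "year", "pesticide", "lbs_per_acre"]
    return out[["participant_id", "location", "pesticide", "year", "lbs_per_acre"]]


def window_average(annual: pd.DataFrame, participants: pd.DataFrame,
                   window_start: int = WINDOW_START,
                   window_offset: int = WINDOW_OFFSET) -> pd.DataFrame:
    """Windowed raw summaries: mean annual lbs/acre over [window_start,
    index_year - window_offset] restricted to address-covered years.

    ``annual`` is the output of :func:`compute_annual_exposures`.  Returns a
    frame indexed by (participant_id, location) with pesticide columns plus a
    ``covered_years`` column; participant-locations with zero covered years
    are absent (their summary is missing, not zero).
    """
    idx = participants.set_index("participant_id")["index_year"]
    years = annual.index.get_level_values("year")
    pid = annual.index.get_level_values("participant_id")
    win_end = pid.map(idx) - window_offset
    keep = (years >= window_start) & (years <= win_end)
    windowed = annual[keep]
    if windowed.empty:
        log.warning("no covered years inside the exposure window for any participant")
        out = pd.DataFrame(columns=list(annual.columns) + ["covered_years"])
        out.index = pd.MultiIndex.from_arrays([[], []], names=["participant_id", "location"])
        return out
    grouped = windowed.groupby(["participant_id", "location"])
    summary = grouped.mean()
    summary["covered_years"] = grouped.size()
    return summary


def transform(raw: pd.Series, strict: bool = True) -> pd.Series:
    """log1p, center, scale to SD within one standardization stratum.

    Missing values stay missing.  Zero variance raises (strict) or returns
    all-missing with a log entry.
    """
    logged = np.log1p(raw.astype(float))
    sd = logged.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        msg = f"zero variance in stratum for {raw.name!r}; cannot standardize"
        if strict:
            raise ValueError(msg)
        log.warning(msg)
        return pd.Series(np.nan, index=raw.index, name=raw.name)
    return (logged - logged.mean()) / sd


@dataclass
class ExposureMatrix:
    """Participants-by-pesticides exposure estimates, one layer per location.

    ``raw`` and ``z`` map location type to wide frames indexed by participant;
    ``covered`` gives covered window years per participant-location.
    """

    raw: dict[str, pd.DataFrame]
    z: dict[str, pd.DataFrame]
    covered: pd.DataFrame
    participants: pd.DataFrame
    pesticides: list[str] = field(default_factory=list)

    def exposed(self) -> pd.DataFrame:
        """Participant x pesticide: raw > 0 at any location layer."""
        frames = []
        for loc, df in self.raw.items():
            frames.append(df > 0)
        out = frames[0]
        for f in frames[1:]:
            out = out.reindex(out.index.union(f.index), fill_value=False) | \
                f.reindex(out.index.union(f.index), fill_value=False)
        return out.fillna(False)

    def exposed_counts(self) -> pd.Series:
        return self.exposed().sum(axis=0).astype(int)

    def inclusion_mask(self, min_exposed: int = 25) -> pd.Series:
        """True for pesticides with at least ``min_exposed`` exposed participants."""
        return self.exposed_counts() >= min_exposed

    def long(self) -> pd.DataFrame:
        rows = []
        for loc in self.raw:
            r = self.raw[loc].stack().rename("raw")
            z = self.z[loc].stack().rename("z")
            df = pd.concat([r, z], axis=1).reset_index()
            df.columns = ["participant_id", "pesticide", "raw", "z"]
            df.insert(1, "location", loc)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def build_exposure_matrix(applications, addresses, parcels, participants,
                          spec: BufferSpec = BufferSpec(),
                          window_start: int = WINDOW_START,
                          window_offset: int = WINDOW_OFFSET) -> ExposureMatrix:
    """Full assessment: annual values -> window averages -> standardized layers.

    Standardization is within wave x location, pooled over cases and controls;
    pesticide-strata with zero variance are left missing with a log entry.
    """
    annual = compute_annual_exposures(applications, addresses, parcels, spec)
    summary = window_average(annual, participants, window_start, window_offset)
    pest_cols = [c for c in summary.columns if c != "covered_years"]
    wave = participants.set_index("participant_id")["wave"]

    raw_layers, z_layers = {}, {}
    for loc in summary.index.get_level_values("location").unique():
        raw = summary.xs(loc, level="location")[pest_cols]
        raw_layers[loc] = raw
        zs = []
        for w, sub in raw.groupby(raw.index.map(wave)):
            zw = pd.DataFrame({c: transform(sub[c], strict=False) for c in pest_cols},
                              index=sub.index)
            zs.append(zw)
        z_layers[loc] = pd.concat(zs).reindex(raw.index)
    covered = summary["covered_years"].unstack("location")
    return ExposureMatrix(raw=raw_layers, z=z_layers, covered=covered,
                          participants=participants, pesticides=pest_cols)
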