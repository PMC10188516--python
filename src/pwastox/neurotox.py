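"""Statistics of the dopaminergic-neuron toxicity screen.

Object-level detections are gated on size (40 < area < 400 square microns,
strict), shape (roundness > 0.7) and brightness (intensity > 500); the
reporter-positive threshold is then set at three SDs above the mean intensity
of gated objects in control wells, and per-well counts of objects above it
are the assay readout.  A condition is called toxic when its mean day-11
count falls more than three SDs below the DMSO control mean.  The module also
computes the Z-prime assay-quality statistic, dose summaries with an
interpolated LD50, the all-combinations co-exposure analysis with Student
t-tests and Benjamini-Hochberg adjustment, and the mito-stress parameters
from oxygen-consumption-rate traces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .association import bh_fdr

AREA_MIN, AREA_MAX = 40.0, 400.0
ROUNDNESS_MIN = 0.7
INTENSITY_MIN = 500.0


# ---------------------------------------------------------------------------
# object filtering and counting


def filter_objects(objects: pd.DataFrame) -> pd.DataFrame:
    """Candidate neurons: strict area window, roundness and brightness gates."""
    for col in ("well_id", "area", "roundness", "intensity"):
        if col not in objects.columns:
            raise KeyError(f"object table missing required column {col!r}")
    keep = ((objects["area"] > AREA_MIN) & (objects["area"] < AREA_MAX)
            & (objects["roundness"] > ROUNDNESS_MIN)
            & (objects["intensity"] > INTENSITY_MIN))
    return objects[keep]


def control_threshold(control_objects: pd.DataFrame) -> float:
    """Reporter-positive cutoff: mean + 3 SD of control candidate intensities."""
    x = control_objects["intensity"].to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least two control objects to set a threshold")
    return float(x.mean() + 3.0 * x.std(ddof=1))


def count_positives(objects: pd.DataFrame, wells: pd.DataFrame,
                    control_role: str = "DMSO") -> pd.DataFrame:
    """Per-well reporter-positive counts (candidates above the control cutoff,
    summed over the well's fields).  Wells without detected objects count 0."""
    candidates = filter_objects(objects)
    ctrl_wells = wells.loc[wells["role"] == control_role, "well_id"]
    if ctrl_wells.empty:
        raise ValueError(f"no wells with control role {control_role!r}")
    cutoff = control_threshold(candidates[candidates["well_id"].isin(ctrl_wells)])
    pos = candidates[candidates["intensity"] > cutoff]
    counts = pos.groupby("well_id").size()
    out = wells.drop_duplicates("well_id").copy()
    out["count"] = out["well_id"].map(counts).fillna(0).astype(int)
    out.attrs["intensity_cutoff"] = cutoff
    return out


# ---------------------------------------------------------------------------
# toxicity calls and assay quality


def toxicity_call(well_counts: pd.DataFrame, timepoint: str | None = "day11",
                  sd_mult: float = 3.0, dose: float | None = None) -> pd.DataFrame:
    """Per-condition toxicity flags against the DMSO distribution.

    A condition (compound, or compound at ``dose`` when given) is toxic when
    its mean count is strictly below mean(DMSO) - sd_mult * SD(DMSO).
    """
    df = well_counts
    if timepoint is not None and "timepoint" in df.columns:
        df = df[df["timepoint"] == timepoint]
    dmso = df.loc[df["role"] == "DMSO", "count"]
    if len(dmso) < 2:
        raise ValueError("need at least two DMSO wells at this timepoint")
    thresh = float(dmso.mean() - sd_mult * dmso.std(ddof=1))
    treated = df[df["role"] == "treated"]
    if dose is not None:
        treated = treated[treated["dose"] == dose]
    rows = []
    for compound, sub in treated.groupby("compound"):
        m = float(sub["count"].mean())
        rows.append({"compound": compound, "mean_count": m,
                     "threshold": thresh, "toxic": m < thresh,
                     "n_wells": len(sub)})
    return pd.DataFrame(rows).sort_values("compound", kind="stable").reset_index(drop=True)


def zprime(negative, positive) -> float:
    """Z' = 1 - 3(sd_pos + sd_neg) / |mean_pos - mean_neg|."""
    neg = np.asarray(negative, dtype=float)
    pos = np.asarray(positive, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need at least two wells per control arm")
    gap = abs(pos.mean() - neg.mean())
    if gap == 0:
        raise ValueError("Z-prime undefined: control means are equal")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / gap)


def dose_summary(well_counts: pd.DataFrame, compound: str,
                 timepoint: str | None = "day11") -> pd.DataFrame:
    """Per-dose mean counts and percent decrease versus DMSO, with a
    log-linearly interpolated LD50 when the 50% level is crossed.

    The LD50 is stored in ``attrs['ld50']`` (nan when not bracketed).
    """
    df = well_counts
    if timepoint is not None and "timepoint" in df.columns:
        df = df[df["timepoint"] == timepoint]
    mu_dmso = df.loc[df["role"] == "DMSO", "count"].mean()
    if not mu_dmso > 0:
        raise ValueError("DMSO mean count must be positive")
    sub = df[(df["compound"] == compound) & (df["role"] == "treated")]
    if sub["dose"].nunique() < 2:
        raise ValueError("need at least two doses for a dose summary")
    means = sub.groupby("dose")["count"].mean().sort_index()
    out = pd.DataFrame({
        "dose": means.index,
        "mean_count": means.to_numpy(),
        "pct_decrease": 100.0 * (mu_dmso - means.to_numpy()) / mu_dmso,
    })
    monotone = bool(np.all(np.diff(means.to_numpy()) <= 0))
    out.attrs["monotone_decreasing"] = monotone
    out.attrs["ld50"] = _interp_ld50(means, mu_dmso)
    return out


def _interp_ld50(means: pd.Series, mu_dmso: float) -> float:
    half = 0.5 * mu_dmso
    doses = means.index.to_numpy(dtype=float)
    vals = means.to_numpy(dtype=float)
    for i in range(len(vals) - 1):
        hi_v, lo_v = vals[i], vals[i + 1]
        if hi_v >= half > lo_v:
            # linear in log-dose between the bracketing doses
            f = (hi_v - half) / (hi_v - lo_v)
            return float(np.exp(np.log(doses[i]) + f * (np.log(doses[i + 1]) - np.log(doses[i]))))
    return float("nan")


# ---------------------------------------------------------------------------
# combinatorial co-exposure


def combo_analysis(combo_wells: pd.DataFrame, compounds: list[str],
                   alpha: float = 0.05, equal_var: bool = True):
    """All-combinations co-exposure statistics.

    ``combo_wells`` needs columns condition ('+'-joined sorted compound names,
    'DMSO' for the empty set), replicate, count, with every one of the 2^k
    subsets present.  Returns (conditions table ordered by descending mean
    count, pairwise-tests table).  Each multi-compound subset is compared by
    Student's t-test with each constituent singleton and with DMSO; q-values
    are BH-adjusted over all comparisons.  A two-compound subset is flagged
    'enhanced toxicity' when it is significantly lower (q < alpha) than both
    of its constituents.
    """
    expected = {"DMSO"}
    for r in range(1, len(compounds) + 1):
        for sub in itertools.combinations(sorted(compounds), r):
            expected.add("+".join(sub))
    present = set(combo_wells["condition"])
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"missing combination conditions: {missing}")

    groups = {c: g["count"].to_numpy(dtype=float)
              for c, g in combo_wells.groupby("condition")}
    if min(len(v) for v in groups.values()) < 2:
        raise ValueError("need at least two replicates per condition")
    mu_dmso = groups["DMSO"].mean()

    cond_rows = []
    for cond in sorted(expected):
        v = groups[cond]
        cond_rows.append({
            "condition": cond,
            "n_compounds": 0 if cond == "DMSO" else cond.count("+") + 1,
            "mean_count": v.mean(),
            "pct_decrease": 100.0 * (mu_dmso - v.mean()) / mu_dmso,
            "n_replicates": len(v),
        })
    conditions = (pd.DataFrame(cond_rows)
                  .sort_values(["mean_count", "condition"], ascending=[False, True],
                               kind="stable")
                  .reset_index(drop=True))

    test_rows = []
    for cond in sorted(expected - {"DMSO"}):
        parts = cond.split("+")
        if len(parts) < 2:
            refs = ["DMSO"]
        else:
            refs = parts + ["DMSO"]
        for ref in refs:
            t, p = ttest_ind(groups[cond], groups[ref], equal_var=equal_var)
            test_rows.append({"condition": cond, "reference": ref,
                              "t": float(t), "p": float(p),
                              "lower": groups[cond].mean() < groups[ref].mean()})
    tests = pd.DataFrame(test_rows)
    tests["q"] = bh_fdr(tests["p"])

    flags = []
    for cond in sorted(expected):
        parts = cond.split("+")
        if cond == "DMSO" or len(parts) != 2:
            flags.append((cond, False))
            continue
        sub = tests[(tests["condition"] == cond) & (tests["reference"] != "DMSO")]
        flags.append((cond, bool(((sub["q"] < alpha) & sub["lower"]).all()
                                 and len(sub) == 2)))
    conditions = conditions.merge(
        pd.DataFrame(flags, columns=["condition", "enhanced_toxicity"]),
        on="condition")
    return conditions, tests


# ---------------------------------------------------------------------------
# mito-stress parameters


@dataclass
class MitoParams:
    non_mito: float
    basal: float
    atp_linked: float
    maximal: float
    spare: float
    spare_pct: float
    flagged: bool = False

    def as_dict(self) -> dict:
        return {"non_mito": self.non_mito, "basal": self.basal,
                "atp_linked": self.atp_linked, "maximal": self.maximal,
                "spare": self.spare, "spare_pct": self.spare_pct,
                "flagged": self.flagged}


def mito_stress(trace: pd.DataFrame) -> MitoParams:
    """Mito-stress parameters from one OCR trace.

    Segment conventions (vendor-standard cycle selections): non-mitochondrial
    respiration is the minimum after rotenone/antimycin-A; basal uses the last
    pre-oligomycin cycle; ATP-linked is last pre-oligomycin minus the
    post-oligomycin minimum; maximal is the post-FCCP maximum minus
    non-mitochondrial.  ``spare = maximal - basal`` identically.
    """
    needed = {"basal", "oligomycin", "fccp", "rot_aa"}
    seg = {s: g.sort_values("cycle")["ocr"].to_numpy(dtype=float)
           for s, g in trace.groupby("segment")}
    missing = needed - set(seg)
    if missing:
        raise ValueError(f"trace missing segments: {sorted(missing)}")
    non_mito = float(seg["rot_aa"].min())
    last_basal = float(seg["basal"][-1])
    basal = last_basal - non_mito
    atp = last_basal - float(seg["oligomycin"].min())
    maximal = float(seg["fccp"].max()) - non_mito
    spare = maximal - basal
    spare_pct = 100.0 * maximal / basal if basal != 0 else float("nan")
    return MitoParams(non_mito, basal, atp, maximal, spare, spare_pct,
                      flagged=not basal > 0)


def mito_stress_table(traces: pd.DataFrame) -> pd.DataFrame:
    """Parameters for every trace_id in a trace table."""
    rows = []
    for tid, g in traces.groupby("trace_id"):
        rows.append({"trace_id": tid, **mito_stress(g).as_dict()})
    return pd.DataFrame(rows)
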