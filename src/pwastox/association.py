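"""Pesticide-wide association study statistics.

Per pesticide we fit univariate unconditional logistic regressions of
case status on standardized exposure within each wave-by-location stratum,
pool the stratum log-ORs by inverse-variance fixed-effects meta-analysis
(two-sided z-score p-values), and control the FDR across pesticides with
Benjamini-Hochberg.  Group overrepresentation uses the Fisher exact
framework with the conditional maximum-likelihood odds ratio and the exact
confidence interval obtained by inverting the noncentral hypergeometric
tails at 2.5% each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import fisher_exact, nchypergeom_fisher, norm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

Z95 = norm.ppf(0.975)


# ---------------------------------------------------------------------------
# stratum fits and meta-analysis


@dataclass
class StratumFit:
    pesticide: str
    stratum: str
    beta: float
    se: float
    n: int
    converged: bool = True
    note: str = ""

    @property
    def usable(self) -> bool:
        return self.converged and np.isfinite(self.beta) and np.isfinite(self.se) \
            and self.se > 0


@dataclass
class MetaResult:
    pesticide: str
    beta: float
    se: float
    z: float
    p: float
    or_: float
    ci_low: float
    ci_high: float
    n_strata: int
    q: float = np.nan


def fit_logistic(outcome, exposure, covariates=None, pesticide: str = "",
                 stratum: str = "") -> StratumFit:
    """ML logistic fit of a binary outcome on standardized exposure.

    Covariates are optional (the default, covariate-free fit matches the
    univariate screening model); separation or non-convergence yields a
    flagged fit that the meta-analysis skips.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    X = [x[keep]]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        X += [cov[keep, j] for j in range(cov.shape[1])]
    y = y[keep]
    n = int(keep.sum())
    if n == 0 or y.min() == y.max():
        return StratumFit(pesticide, stratum, np.nan, np.nan, n, False,
                          "needs at least one case and one control")
    design = sm.add_constant(np.column_stack(X))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=0, maxiter=200, warn_convergence=False)
        beta, se = float(res.params[1]), float(res.bse[1])
        ok = bool(res.mle_retvals.get("converged", False)) and np.isfinite(se) \
            and se < 50.0
        return StratumFit(pesticide, stratum, beta, se, n, ok,
                          "" if ok else "non-convergence or separation")
    except Exception as exc:  # perfect separation raises in statsmodels
        return StratumFit(pesticide, stratum, np.nan, np.nan, n, False, str(exc))


def meta_fixed(fits: list[StratumFit]) -> MetaResult | None:
    """Inverse-variance-weighted fixed-effects pooling of usable stratum fits."""
    usable = [f for f in fits if f.usable]
    if not usable:
        return None
    w = np.array([1.0 / f.se**2 for f in usable])
    b = np.array([f.beta for f in usable])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = 2.0 * norm.sf(abs(z))
    return MetaResult(
        pesticide=usable[0].pesticide, beta=beta, se=se, z=z, p=p,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        n_strata=len(usable),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (missing p stays missing)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# PWAS driver


def _stratum_frames(expo, participants):
    """Yield (stratum label, wave, location, outcome Series, z frame, raw frame)."""
    meta = participants.set_index("participant_id")
    for loc in sorted(expo.z):
        zloc, rloc = expo.z[loc], expo.raw[loc]
        for wave in sorted(meta["wave"].unique()):
            members = meta.index[meta["wave"] == wave].intersection(zloc.index)
            if len(members) == 0:
                continue
            yield (f"{wave}:{loc}", wave, loc, meta.loc[members, "case"],
                   zloc.loc[members], rloc.loc[members])


def run_pwas(expo, participants, min_exposed: int = 25,
             fdr_tiers: tuple[float, float, float] = (0.01, 0.05, 0.10),
             covariates: list[str] | None = None) -> pd.DataFrame:
    """The pesticide-wide screen.

    Pesticides with fewer than ``min_exposed`` exposed participants are
    excluded.  A stratum contributes only if the pesticide has at least one
    exposed case and one exposed control there.  Returns one row per included
    pesticide with pooled OR, CI, p, q, and tier labels
    (``fdr<=t1``, ``t1<fdr<=t2``, ``t2<fdr<t3``, ``ns``).
    """
    mask = expo.inclusion_mask(min_exposed)
    included = [p for p in expo.pesticides if mask.get(p, False)]
    meta_cov = participants.set_index("participant_id")
    rows = []
    for pest in included:
        fits = []
        for label, wave, loc, y, z, raw in _stratum_frames(expo, participants):
            exp_flag = raw[pest] > 0
            if not ((exp_flag & (y == 1)).any() and (exp_flag & (y == 0)).any()):
                continue
            cov = None
            if covariates:
                cov = meta_cov.loc[y.index, covariates].to_numpy(float)
            fits.append(fit_logistic(y, z[pest], cov, pest, label))
        res = meta_fixed(fits)
        if res is None:
            log.info("pesticide %s: no usable strata, missing meta row", pest)
            continue
        row = {"pesticide": pest, "beta": res.beta, "se": res.se, "z": res.z,
               "p": res.p, "or": res.or_, "ci_low": res.ci_low,
               "ci_high": res.ci_high, "n_strata": res.n_strata,
               "n_exposed": int(expo.exposed_counts()[pest])}
        for f in fits:
            row[f"beta[{f.stratum}]"] = f.beta if f.usable else np.nan
            row[f"se[{f.stratum}]"] = f.se if f.usable else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_fdr(out["p"])
    t1, t2, t3 = fdr_tiers
    out["tier"] = np.select(
        [out["q"] <= t1, out["q"] <= t2, out["q"] < t3],
        [f"fdr<={t1}", f"{t1}<fdr<={t2}", f"{t2}<fdr<{t3}"], default="ns")
    out["implicated"] = out["q"] < t3
    out["associated"] = out["q"] <= t2
    return out.sort_values("q", kind="stable").reset_index(drop=True)


def tier_percentages(counts, total: int) -> list[float]:
    """Percent of tested pesticides per tier, from tier counts."""
    if total <= 0:
        raise ValueError("total tested must be positive")
    return [100.0 * c / total for c in counts]


def interaction_test(expo, participants, pesticide: str,
                     modifier: str = "gender") -> dict:
    """Exposure-by-modifier interaction: per-stratum Wald test on the product
    term, meta-combined by inverse variance.  Single-level or zero-exposure-
    variance strata are flagged and skipped."""
    meta = participants.set_index("participant_id")
    fits, flagged = [], []
    for label, wave, loc, y, z, raw in _stratum_frames(expo, participants):
        mod = meta.loc[y.index, modifier]
        m = (mod == "M").astype(float) if mod.dtype == object else mod.astype(float)
        x = z[pesticide]
        if m.nunique() < 2:
            flagged.append((label, "single modifier level"))
            continue
        sd_by_level = x.groupby(m).std(ddof=1)
        if not np.isfinite(sd_by_level.min()) or sd_by_level.min() == 0:
            flagged.append((label, "no exposure variance in one level"))
            continue
        keep = x.notna()
        design = sm.add_constant(np.column_stack([x[keep], m[keep], x[keep] * m[keep]]))
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y[keep].astype(float), design).fit(
                    disp=0, maxiter=200, warn_convergence=False)
            beta = float(np.asarray(res.params)[3])
            se = float(np.asarray(res.bse)[3])
            if res.mle_retvals.get("converged", False) and np.isfinite(se) and se < 50:
                fits.append(StratumFit(pesticide, label, beta, se, int(keep.sum())))
            else:
                flagged.append((label, "non-convergence"))
        except Exception as exc:
            flagged.append((label, str(exc)))
    pooled = meta_fixed(fits)
    return {
        "pesticide": pesticide,
        "beta_interaction": pooled.beta if pooled else np.nan,
        "se_interaction": pooled.se if pooled else np.nan,
        "p_interaction": pooled.p if pooled else np.nan,
        "n_strata": len(fits),
        "flagged": flagged,
    }


# ---------------------------------------------------------------------------
# Fisher exact framework / overrepresentation analysis


def _nch(table, odds):
    a, b = table[0]
    c, d = table[1]
    M, n, N = a + b + c + d, a + c, a + b
    return nchypergeom_fisher(M, n, N, odds)


def conditional_mle_or(table) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table.

    The MLE under the noncentral hypergeometric law for the top-left cell
    given all margins; 0 and inf at the support boundaries.
    """
    (a, b), (c, d) = table
    amin, amax = max(0, a - d), min(a + b, a + c)
    if a == amax:
        return np.inf
    if a == amin:
        return 0.0

    def mean_gap(logpsi):
        return _nch(table, np.exp(logpsi)).mean() - a

    return float(np.exp(brentq(mean_gap, -50, 50, xtol=1e-12)))


def exact_or_ci(table, alpha: float = 0.05) -> tuple[float, float]:
    """Exact CI by inverting the noncentral hypergeometric tail probabilities
    at alpha/2 each side."""
    (a, b), (c, d) = table
    amin, amax = max(0, a - d), min(a + b, a + c)
    half = alpha / 2.0

    def sf_at(logpsi):   # P(X >= a | psi) - half, increasing in psi
        return _nch(table, np.exp(logpsi)).sf(a - 1) - half

    def cdf_at(logpsi):  # P(X <= a | psi) - half, decreasing in psi
        return _nch(table, np.exp(logpsi)).cdf(a) - half

    lo = 0.0 if a == amin else float(np.exp(brentq(sf_at, -50, 50, xtol=1e-12)))
    hi = np.inf if a == amax else float(np.exp(brentq(cdf_at, -50, 50, xtol=1e-12)))
    return lo, hi


def ora(associated: set, annotations: pd.DataFrame,
        universe: set | None = None) -> pd.DataFrame:
    """Group overrepresentation in the associated pesticide set.

    ``annotations`` is long (columns ``pesticide``, ``group``); the universe
    defaults to all annotated pesticides, and any supplied universe members
    without annotations are dropped.  Per group: 2x2 counts, two-sided Fisher
    exact p (summation of table probabilities at or below the observed one),
    conditional-MLE OR with exact 95% CI, and BH q across groups.
    """
    annotated = set(annotations["pesticide"])
    if universe is None:
        universe = annotated
    else:
        dropped = set(universe) - annotated
        if dropped:
            log.info("dropping %d universe members without annotations", len(dropped))
        universe = set(universe) & annotated
    assoc = set(associated) & universe
    rows = []
    for group, sub in annotations.groupby("group"):
        members = set(sub["pesticide"]) & universe
        if not members:
            log.info("group %s empty within universe; skipped", group)
            continue
        a = len(assoc & members)
        b = len(assoc - members)
        c = len(members - assoc)
        d = len(universe) - a - b - c
        table = [[a, b], [c, d]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        lo, hi = exact_or_ci(table)
        rows.append({"group": group, "a": a, "b": b, "c": c, "d": d,
                     "or": conditional_mle_or(table), "ci_low": lo, "ci_high": hi,
                     "p": p,
                     "pct_of_group_associated": 100.0 * a / (a + c),
                     "pct_of_universe": 100.0 * (a + c) / len(universe)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_fdr(out["p"])
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
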