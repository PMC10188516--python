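"""Co-exposure structure among implicated pesticides.

Pairwise Pearson correlations of (transformed residential) exposures feed a
two-layer network -- neurotoxic versus other implicated pesticides, keeping
only cross-layer edges above a correlation threshold -- and an agglomerative
clustering on distance 1 - R cut at a fixed height.  With complete linkage
the default cut height of 0.55 guarantees every within-cluster pair is
correlated at R >= 0.45, matching the network threshold.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


def corr_matrix(values: pd.DataFrame, pesticides: list[str] | None = None,
                min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations over the given pesticide set.

    Zero-variance pesticides get missing rows/columns (logged).
    """
    if pesticides is not None:
        values = values[list(pesticides)]
    flat = values.std(ddof=1) == 0
    if flat.any():
        log.warning("zero-variance pesticides excluded from correlations: %s",
                    list(values.columns[flat]))
    r = values.corr(min_periods=min_periods)
    r.loc[flat, :] = np.nan
    r.loc[:, flat] = np.nan
    np.fill_diagonal(r.values, np.where(flat, np.nan, 1.0))
    return r


def build_network(corr: pd.DataFrame, toxic: set, threshold: float = 0.45,
                  fdr: dict | None = None):
    """Two-layer co-exposure graph.

    Edges connect a neurotoxic pesticide to a non-toxic one when their
    correlation exceeds ``threshold`` (within-layer correlations are not
    represented).  Returns (graph, nodes table ordered by descending
    cross-layer degree, summary dict).  Node attributes: layer, degree,
    closeness centrality on the retained (edge-bearing) subgraph, and the
    screening FDR when provided.
    """
    toxic = set(toxic) & set(corr.index)
    if not toxic:
        raise ValueError("toxic set is empty (or disjoint from the matrix ids)")
    other = [p for p in corr.index if p not in toxic]
    g = nx.Graph()
    for p in corr.index:
        g.add_node(p, layer="mDA-toxic" if p in toxic else "other",
                   fdr=(fdr or {}).get(p, np.nan))
    for t in sorted(toxic):
        for o in other:
            r = corr.at[t, o]
            if np.isfinite(r) and r > threshold:
                g.add_edge(t, o, weight=float(r))
    retained = g.edge_subgraph(g.edges).copy()
    closeness = nx.closeness_centrality(retained) if retained.number_of_edges() else {}
    rows = []
    for p in g.nodes:
        rows.append({"pesticide": p, "layer": g.nodes[p]["layer"],
                     "degree": g.degree(p),
                     "closeness": closeness.get(p, 0.0),
                     "fdr": g.nodes[p]["fdr"]})
    nodes = (pd.DataFrame(rows)
             .sort_values(["degree", "pesticide"], ascending=[False, True],
                          kind="stable")
             .reset_index(drop=True))
    n_other = len(other)
    linked = sum(1 for o in other if g.degree(o) > 0)
    summary = {
        "n_toxic": len(toxic),
        "n_other": n_other,
        "frac_other_linked_to_toxic": linked / n_other if n_other else np.nan,
    }
    return g, nodes, summary


def cluster(corr: pd.DataFrame, height: float = 0.55,
            method: str = "complete") -> pd.Series:
    """Agglomerative clustering on distance 1 - R, cut at ``height``.

    Cluster labels are deterministic: numbered by decreasing cluster size,
    ties broken by the lexically smallest member.  Raises on missing entries
    (recompute the matrix pairwise-complete over a reduced set first).
    """
    if corr.isna().any().any():
        raise ValueError(
            "correlation matrix has missing entries; recompute pairwise-complete "
            "over the pesticides with data before clustering"
        )
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    if len(corr) == 1:
        return pd.Series([1], index=corr.index, name="cluster")
    lab = fcluster(linkage(squareform(d, checks=False), method=method),
                   t=height, criterion="distance")
    s = pd.Series(lab, index=corr.index, name="cluster")
    order = sorted(s.groupby(s).groups.items(),
                   key=lambda kv: (-len(kv[1]), sorted(kv[1])[0]))
    remap = {old: i + 1 for i, (old, _) in enumerate(order)}
    return s.map(remap).rename("cluster")


def share_on_crop(applications: pd.DataFrame, pesticide: str, crop: str) -> float:
    """Proportion of a pesticide's application records on the given crop."""
    recs = applications[applications["pesticide"] == pesticide]
    if recs.empty:
        log.warning("no application records for pesticide %s", pesticide)
        return np.nan
    return float((recs["crop"] == crop).mean())


def crop_share_table(applications: pd.DataFrame, crop: str,
                     pesticides: list[str] | None = None) -> pd.DataFrame:
    """Per-pesticide share of application records on one crop, descending."""
    pests = pesticides if pesticides is not None else sorted(set(applications["pesticide"]))
    rows = [{"pesticide": p, "crop": crop,
             "share": share_on_crop(applications, p, crop)} for p in pests]
    return (pd.DataFrame(rows)
            .sort_values(["share", "pesticide"], ascending=[False, True], kind="stable")
            .reset_index(drop=True))
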