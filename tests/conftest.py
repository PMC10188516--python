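"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from pwastox.config import default_config
from pwastox.pipeline import RunConfig, run_all


def raster_fraction(cx, cy, r, x0, y0, x1, y1, step=1.0):
    """Brute-force raster estimate of the disc/rectangle overlap fraction."""
    xs = np.arange(x0 + step / 2, x1, step)
    ys = np.arange(y0 + step / 2, y1, step)
    if xs.size == 0 or ys.size == 0:
        return 0.0
    X, Y = np.meshgrid(xs, ys)
    return float(((X - cx) ** 2 + (Y - cy) ** 2 <= r * r).mean())


def oracle_conditional_mle(a, b, c, d):
    """Exhaustive noncentral-hypergeometric conditional MLE by bisection."""
    n1, n0, m1 = a + b, c + d, a + c
    lo_k, hi_k = max(0, m1 - n0), min(n1, m1)
    ks = np.arange(lo_k, hi_k + 1)
    logw = np.array([np.log(comb(n1, int(k))) + np.log(comb(n0, int(m1 - k)))
                     for k in ks])

    def mean(logpsi):
        lw = logw + ks * logpsi
        lw -= lw.max()
        w = np.exp(lw)
        return float((ks * w).sum() / w.sum())

    if a == hi_k:
        return np.inf
    if a == lo_k:
        return 0.0
    lo, hi = -60.0, 60.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if mean(mid) < a:
            lo = mid
        else:
            hi = mid
    return float(np.exp((lo + hi) / 2))


def oracle_bh(p):
    """Direct Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def adjusted_rand_index(labels_a, labels_b):
    """Pair-counting adjusted Rand index."""
    ct = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b)).to_numpy()
    s = sum(comb(int(x), 2) for x in ct.ravel())
    sa = sum(comb(int(x), 2) for x in ct.sum(axis=1))
    sb = sum(comb(int(x), 2) for x in ct.sum(axis=0))
    n = comb(int(ct.sum()), 2)
    expected = sa * sb / n
    maximum = (sa + sb) / 2
    return (s - expected) / (maximum - expected)


def complete_linkage_partition(dist, height):
    """Naive agglomerative complete-linkage clustering cut at ``height``.

    ``dist`` is a symmetric (n, n) distance array; returns the partition as a
    set of frozensets of indices.
    """
    clusters = [frozenset([i]) for i in range(dist.shape[0])]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best[0] > height:
            break
        d, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return set(clusters)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run at demo scale, shared across pipeline tests."""
    out = tmp_path_factory.mktemp("demo_run")
    cfg = default_config(seed=7)
    manifest = run_all(cfg, RunConfig(outdir=out))
    return out, cfg, manifest
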