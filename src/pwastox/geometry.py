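"""Exact circle-rectangle overlap areas for axis-aligned parcels.

The exposure pipeline intersects address buffers with parcel polygons using
general polygon arithmetic (shapely, with the disc approximated by a 64-gon).
This module provides the closed-form area of intersection between a disc and
an axis-aligned rectangle, used by the synthetic-data generator to record
ground-truth exposures through an independent code path, and by the tests as
an analytic oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = ["circle_rect_overlap"]


def _antideriv(t: np.ndarray, r: float) -> np.ndarray:
    # antiderivative of sqrt(r^2 - t^2); t must already lie in [-r, r]
    t = np.clip(t, -r, r)
    return 0.5 * (t * np.sqrt(np.maximum(r * r - t * t, 0.0)) + r * r * np.arcsin(t / r))


def _corner_area(x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    """Area of disc(0, 0, r) intersected with the quadrant {X <= x, Y <= y}."""
    x = np.clip(np.asarray(x, dtype=float), -r, r)
    y = np.clip(np.asarray(y, dtype=float), -r, r)
    tstar = np.sqrt(np.maximum(r * r - y * y, 0.0))

    def seg_full(a, b):
        # integral of 2*sqrt(r^2-t^2) over [a, b], empty if b <= a
        b = np.maximum(a, b)
        return 2.0 * (_antideriv(b, r) - _antideriv(a, r))

    def seg_chord(a, b, yy):
        b = np.maximum(a, b)
        return yy * (b - a) + (_antideriv(b, r) - _antideriv(a, r))

    # y >= 0: full chords for |t| > tstar, capped chords for |t| <= tstar
    pos = (
        seg_full(np.full_like(x, -r), np.minimum(x, -tstar))
        + seg_chord(-tstar, np.minimum(x, tstar), y)
        + seg_full(tstar, x)
    )
    # y < 0: only |t| <= tstar contributes
    neg = seg_chord(-tstar, np.minimum(x, tstar), y)
    return np.where(y >= 0.0, pos, neg)


def circle_rect_overlap(cx, cy, r: float, x0, y0, x1, y1):
    """Exact area of intersection of disc((cx, cy), r) with [x0, x1] x [y0, y1].

    All arguments may be scalars or broadcastable arrays; coordinates are in
    the same planar metric system (meters).
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    cx, cy, x0, y0, x1, y1 = np.broadcast_arrays(
        *[np.asarray(v, dtype=float) for v in (cx, cy, x0, y0, x1, y1)]
    )
    a = (
        _corner_area(x1 - cx, y1 - cy, r)
        - _corner_area(x0 - cx, y1 - cy, r)
        - _corner_area(x1 - cx, y0 - cy, r)
        + _corner_area(x0 - cx, y0 - cy, r)
    )
    out = np.maximum(a, 0.0)
    return float(out) if out.ndim == 0 else out
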