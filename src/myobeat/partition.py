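"""Assign regional labels to sarcomeres from the tissue rectangle axes.

Each sarcomere midpoint is expressed in normalized rectangle coordinates
(u along the long axis, v along the short axis, both in [0, 1]) and
binned into a longitudinal third and a transverse half.  Anchoring is
chosen so labels are stable across the frames of one movie: u = 0 at
the rectangle end with the smaller column coordinate, v = 0 at the side
with the smaller row coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Sarcomere
from .errors import ConsistencyError
from .segment import TissueMask

__all__ = ["RegionLabel", "assign_regions", "REGION_SELECTORS", "region_filter"]

# tolerance (in normalized units) for midpoints just outside the
# rectangle, absorbing blur-induced shrinkage of the fitted rectangle
OUTSIDE_TOL = 0.02

LONGITUDINAL = ("left", "center", "right")
TRANSVERSE = ("top", "bottom")
REGION_SELECTORS = (
    ("whole",)
    + LONGITUDINAL
    + TRANSVERSE
    + tuple(f"{lo}-{tr}" for lo in LONGITUDINAL for tr in TRANSVERSE)
)


@dataclass(frozen=True)
class RegionLabel:
    longitudinal: str   # left | center | right
    transverse: str     # top | bottom


def _rect_axes(mask: TissueMask):
    th = np.deg2rad(mask.rect_angle)
    long_axis = np.array([np.sin(th), np.cos(th)])   # (d_row, d_col)
    short_axis = np.array([np.cos(th), -np.sin(th)])
    center = np.asarray(mask.rect_center)
    long_len, short_len = mask.rect_dims

    e0 = center - 0.5 * long_len * long_axis
    e1 = center + 0.5 * long_len * long_axis
    if (e1[1], e1[0]) < (e0[1], e0[0]):   # anchor u=0 at the smaller-column end
        e0, long_axis = e1, -long_axis

    s0 = center - 0.5 * short_len * short_axis
    s1 = center + 0.5 * short_len * short_axis
    if (s1[0], s1[1]) < (s0[0], s0[1]):   # anchor v=0 at the smaller-row side
        s0, short_axis = s1, -short_axis
    return e0, long_axis, long_len, s0, short_axis, short_len


def rect_coordinates(points_rc: np.ndarray, mask: TissueMask) -> np.ndarray:
    """Normalized (u, v) coordinates of (row, col) points in the rectangle frame."""
    e0, la, ll, s0, sa, sl = _rect_axes(mask)
    pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
    u = (pts - e0) @ la / ll
    v = (pts - s0) @ sa / sl
    return np.column_stack([u, v])


def _bin(u: float, v: float) -> RegionLabel:
    u = min(max(u, 0.0), 1.0)
    v = min(max(v, 0.0), 1.0)
    if u < 1.0 / 3.0:
        lo = "left"
    elif u < 2.0 / 3.0:
        lo = "center"
    else:
        lo = "right"
    tr = "top" if v < 0.5 else "bottom"
    return RegionLabel(longitudinal=lo, transverse=tr)


def assign_regions(
    sarcomeres: list[Sarcomere], mask: TissueMask, tol: float = OUTSIDE_TOL
) -> tuple[list[tuple[Sarcomere, RegionLabel]], int]:
    """Label each sarcomere; returns (labelled pairs, dropped count).

    Sarcomeres whose midpoint falls outside the rectangle by more than
    ``tol`` in either normalized coordinate are dropped.
    """
    if not sarcomeres:
        return [], 0
    if any(s.frame_index != mask.frame_index for s in sarcomeres):
        raise ConsistencyError("sarcomeres and mask are from different frames")

    uv = rect_coordinates(np.array([s.midpoint for s in sarcomeres]), mask)
    labelled, dropped = [], 0
    for s, (u, v) in zip(sarcomeres, uv):
        if u < -tol or u > 1 + tol or v < -tol or v > 1 + tol:
            dropped += 1
            continue
        labelled.append((s, _bin(u, v)))
    return labelled, dropped


def region_filter(selector: str):
    """Predicate on a RegionLabel for a region selector string."""
    if selector == "whole":
        return lambda lab: True
    if selector in LONGITUDINAL:
        return lambda lab: lab.longitudinal == selector
    if selector in TRANSVERSE:
        return lambda lab: lab.transverse == selector
    if "-" in selector:
        lo, tr = selector.split("-", 1)
        if lo in LONGITUDINAL and tr in TRANSVERSE:
            return lambda lab: lab.longitudinal == lo and lab.transverse == tr
    raise ValueError(f"unknown region selector {selector!r}")
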