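"""Per-frame tissue segmentation: noise suppression, blur, Otsu, convex
hull and minimum-area rotated bounding rectangle."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint
from skimage.filters import gaussian, threshold_otsu

from .errors import ParameterError, SegmentationFailure

__all__ = ["SegmentConfig", "TissueMask", "estimate_background_noise", "segment_tissue"]


@dataclass(frozen=True)
class SegmentConfig:
    """noise_patch is (row0, col0, rows, cols); pixels below
    mean + noise_k * sd of the patch are zeroed before blurring."""

    noise_patch: tuple[int, int, int, int] = (0, 0, 20, 20)
    noise_k: float = 3.0
    blur_sigma: float = 2.0

    def validate(self) -> None:
        if self.blur_sigma <= 0:
            raise ParameterError("blur_sigma must be > 0")
        r0, c0, nr, nc = self.noise_patch
        if min(r0, c0) < 0 or nr * nc < 16:
            raise ParameterError("noise_patch must be in-bounds and >= 16 px")


@dataclass(frozen=True)
class TissueMask:
    frame_index: int
    foreground: np.ndarray                 # binary mask
    hull_vertices: np.ndarray              # (k, 2) of (row, col)
    hull_area: float                       # px^2
    rect_center: tuple[float, float]       # (row, col)
    rect_dims: tuple[float, float]         # (long, short) px
    rect_angle: float                      # degrees of the long axis from the column axis, (-90, 90]
    rect_area: float                       # px^2


def estimate_background_noise(frame: np.ndarray, patch: tuple[int, int, int, int]) -> tuple[float, float]:
    """Sample mean and sd of a rectangular background patch."""
    frame = np.asarray(frame, dtype=float)
    r0, c0, nr, nc = patch
    if r0 < 0 or c0 < 0 or r0 + nr > frame.shape[0] or c0 + nc > frame.shape[1]:
        raise ParameterError("noise patch out of bounds")
    if nr * nc < 16:
        raise ParameterError("noise patch must contain at least 16 px")
    vals = frame[r0 : r0 + nr, c0 : c0 + nc].ravel()
    sd = float(np.std(vals, ddof=1))
    return float(np.mean(vals)), sd


def _min_area_rect(points_rc: np.ndarray):
    """Minimum-area rotated rectangle of (row, col) points.

    Returns (center_rc, (long, short), angle_deg) with the angle of the
    long axis measured from the column axis, mapped into (-90, 90].
    """
    xy = points_rc[:, ::-1]  # (col, row) -> (x, y)
    rect = MultiPoint([tuple(p) for p in xy]).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:-1]
    if coords.shape[0] != 4:
        raise ValueError("degenerate rectangle")
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if l1 >= l2:
        long_len, short_len, long_edge = l1, l2, e1
    else:
        long_len, short_len, long_edge = l2, l1, e2
    angle = np.rad2deg(np.arctan2(long_edge[1], long_edge[0]))
    angle = (angle + 90.0) % 180.0 - 90.0
    if angle == -90.0:
        angle = 90.0
    cx, cy = coords.mean(axis=0)
    return (float(cy), float(cx)), (float(long_len), float(short_len)), float(angle)


def segment_tissue(frame: np.ndarray, cfg: SegmentConfig, frame_index: int = 0) -> TissueMask:
    """Segment one frame.  Deterministic and idempotent; frames are
    independent, so calls can run in any order or in parallel."""
    cfg.validate()
    frame = np.asarray(frame, dtype=float)
    mean, sd = estimate_background_noise(frame, cfg.noise_patch)
    suppressed = np.where(frame < mean + cfg.noise_k * sd, 0.0, frame)
    if not np.any(suppressed > 0):
        raise SegmentationFailure(frame_index, "no pixel above the noise-suppression threshold")
    blurred = gaussian(suppressed, sigma=cfg.blur_sigma, preserve_range=True)

    thr = threshold_otsu(blurred)
    fg = blurred > thr
    if not np.any(fg):
        raise SegmentationFailure(frame_index, "empty foreground after Otsu binarization")

    coords = np.argwhere(fg).astype(float)
    try:
        hull = ConvexHull(coords)
    except QhullError as exc:  # collinear / degenerate foreground
        raise SegmentationFailure(frame_index, f"degenerate foreground: {exc}") from exc
    hull_vertices = coords[hull.vertices]
    hull_area = float(hull.volume)  # 2-D ConvexHull: volume is the area

    center, dims, angle = _min_area_rect(hull_vertices)
    return TissueMask(
        frame_index=frame_index,
        foreground=fg,
        hull_vertices=hull_vertices,
        hull_area=hull_area,
        rect_center=center,
        rect_dims=dims,
        rect_angle=angle,
        rect_area=float(dims[0] * dims[1]),
    )
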