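"""Frame-by-frame z-disc detection and pairing into sarcomeres.

Detection is a difference-of-Gaussians band-pass at z-disc scale,
thresholded at a quantile of the positive response, followed by
connected components.  Pairing keeps mutually-best partners whose
separation is physiologic and whose connecting vector is roughly
perpendicular to both discs' major axes.  There is no temporal
tracking: every frame is processed independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import difference_of_gaussians
from skimage.measure import label, regionprops

from .errors import ConsistencyError, InputError, ParameterError

__all__ = ["DetectConfig", "ZDisc", "Sarcomere", "detect_zdiscs", "link_sarcomeres"]

# discs with minor/major axis ratio above this are treated as round:
# their orientation is numerically meaningless and the perpendicularity
# constraint is skipped for them
_ROUND_ELONGATION = 0.9

# score penalty converting angular misalignment (rad) into length units (um)
_ANGLE_PENALTY_UM_PER_RAD = 1.0


@dataclass(frozen=True)
class DetectConfig:
    band_sigma_narrow: float = 1.0
    band_sigma_wide: float = 4.0
    zdisc_threshold_quantile: float = 0.6
    min_zdisc_area: int = 10
    min_sarc_len: float = 1.0      # um
    max_sarc_len: float = 3.0      # um
    angle_tolerance: float = float(np.deg2rad(30.0))
    max_zdiscs_per_frame: int = 1500

    def validate(self) -> None:
        if not 0 < self.band_sigma_narrow < self.band_sigma_wide:
            raise ParameterError("require 0 < band_sigma_narrow < band_sigma_wide")
        if not 0 < self.zdisc_threshold_quantile < 1:
            raise ParameterError("zdisc_threshold_quantile must be in (0, 1)")
        if not 0 < self.min_sarc_len < self.max_sarc_len:
            raise ParameterError("require 0 < min_sarc_len < max_sarc_len")
        if self.angle_tolerance <= 0:
            raise ParameterError("angle_tolerance must be > 0")


@dataclass(frozen=True)
class ZDisc:
    """One detected z-disc band in one frame.

    ``orientation`` is the angle of the component's second-moment major
    axis; the unit direction in (row, col) is (cos o, sin o).
    ``elongation`` is the minor/major axis ratio (1 = circular).
    """

    frame_index: int
    centroid: tuple[float, float]   # (row, col), 0-based px
    area: float                     # px^2
    orientation: float              # radians
    elongation: float

    @property
    def major_axis(self) -> np.ndarray:
        return np.array([np.cos(self.orientation), np.sin(self.orientation)])


@dataclass(frozen=True)
class Sarcomere:
    """A mutually-accepted z-disc pair with a physical length."""

    frame_index: int
    zdisc_a: ZDisc
    zdisc_b: ZDisc
    length: float                   # um
    midpoint: tuple[float, float]   # (row, col) px
    axis_angle: float               # radians, connecting-vector direction


def detect_zdiscs(frame: np.ndarray, cfg: DetectConfig, frame_index: int = 0) -> list[ZDisc]:
    """Detect z-discs in a single frame; returns discs sorted by (row, col)."""
    cfg.validate()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise InputError("frame must be a non-empty 2-D array")
    if not np.all(np.isfinite(frame)):
        raise InputError("frame contains non-finite pixels")

    resp = difference_of_gaussians(frame, cfg.band_sigma_narrow, cfg.band_sigma_wide)
    # exclude numerical dust (< 1e-6 of the peak) from the quantile population
    floor = 1e-6 * float(resp.max()) if resp.max() > 0 else 0.0
    positive = resp[resp > floor]
    if positive.size == 0:
        return []
    thr = np.quantile(positive, cfg.zdisc_threshold_quantile)
    mask = resp >= thr

    lbl = label(mask)
    discs = []
    for p in regionprops(lbl, intensity_image=np.clip(resp, 0.0, None)):
        if p.area < cfg.min_zdisc_area:
            continue
        cr, cc = p.centroid_weighted
        elong = (p.axis_minor_length / p.axis_major_length) if p.axis_major_length > 0 else 1.0
        discs.append(
            ZDisc(
                frame_index=frame_index,
                centroid=(float(cr), float(cc)),
                area=float(p.area),
                orientation=float(p.orientation),
                elongation=float(elong),
            )
        )
    discs.sort(key=lambda d: d.centroid)
    return discs


def _misalignment(conn_unit: np.ndarray, disc: ZDisc) -> float:
    """Deviation (rad) of the connecting vector from the disc normal."""
    if disc.elongation >= _ROUND_ELONGATION:
        return 0.0
    c = abs(float(np.dot(conn_unit, disc.major_axis)))
    return float(np.arcsin(min(c, 1.0)))


def link_sarcomeres(zdiscs: list[ZDisc], cfg: DetectConfig, um_per_px: float) -> list[Sarcomere]:
    """Pair z-discs of one frame into sarcomeres.

    Candidate pairs pass the length window and the perpendicularity
    test against both discs; each disc keeps its two best-scoring
    partners (score favours lengths near the candidate median and small
    misalignment, ties broken by the partner's (row, col) order); only
    mutual acceptances are reported, each pair once.
    """
    cfg.validate()
    if um_per_px <= 0:
        raise ParameterError("um_per_px must be > 0")
    n = len(zdiscs)
    if n < 2:
        return []
    frames = {d.frame_index for d in zdiscs}
    if len(frames) > 1:
        raise ConsistencyError("z-discs come from multiple frames")

    pts = np.array([d.centroid for d in zdiscs])
    diff = pts[None, :, :] - pts[:, None, :]
    dist_um = np.linalg.norm(diff, axis=-1) * um_per_px

    candidates: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            L = dist_um[i, j]
            if not cfg.min_sarc_len <= L <= cfg.max_sarc_len:
                continue
            conn = diff[i, j] / (dist_um[i, j] / um_per_px)
            mis_i = _misalignment(conn, zdiscs[i])
            mis_j = _misalignment(conn, zdiscs[j])
            if mis_i > cfg.angle_tolerance or mis_j > cfg.angle_tolerance:
                continue
            candidates[(i, j)] = (L, 0.5 * (mis_i + mis_j))
    if not candidates:
        return []

    median_len = float(np.median([L for L, _ in candidates.values()]))
    scores = {
        pair: abs(L - median_len) + _ANGLE_PENALTY_UM_PER_RAD * mis
        for pair, (L, mis) in candidates.items()
    }

    accepted: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        partners = sorted(
            {j for pair in scores for j in pair if i in pair and j != i},
            key=lambda j: (scores[(min(i, j), max(i, j))], zdiscs[j].centroid),
        )
        accepted[i] = partners[:2]

    sarcs = []
    for (i, j), _ in sorted(scores.items()):
        if j in accepted[i] and i in accepted[j]:
            a, b = zdiscs[i], zdiscs[j]
            mid = (0.5 * (a.centroid[0] + b.centroid[0]), 0.5 * (a.centroid[1] + b.centroid[1]))
            d = diff[i, j]
            sarcs.append(
                Sarcomere(
                    frame_index=a.frame_index,
                    zdisc_a=a,
                    zdisc_b=b,
                    length=float(dist_um[i, j]),
                    midpoint=mid,
                    axis_angle=float(np.arctan2(d[0], d[1])),
                )
            )
    return sarcs
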