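"""Synthetic beating-tissue movies and sarcomere-length waveforms with ground truth.

The generator produces a rotated rectangular tissue of bright stripes
(z-disc bands perpendicular to the long axis) whose center-to-center
spacing follows a prescribed contraction waveform, so every downstream
stage can be validated against known truth without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .errors import GeometryError, ParameterError

__all__ = [
    "WaveformParams",
    "TissueGeometry",
    "Waveform",
    "generate_length_waveform",
    "render_movie",
    "write_movie",
]


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of one periodic contraction waveform.

    Each cycle is a plateau at ``resting_length`` for ``plateau_duration``
    seconds, a ramp down by ``amplitude`` over ``contraction_duration``,
    and a ramp back up over ``expansion_duration``.  The three durations
    sum to ``period``.  ``ramp`` selects raised-cosine (C1-smooth) or
    linear ramps; the linear option exists for analytic phase tests.
    """

    resting_length: float = 2.0
    amplitude: float = 0.4
    period: float = 1.0
    contraction_duration: float = 0.2
    expansion_duration: float = 0.3
    n_cycles: int = 5
    fps: float = 100.0
    noise_sd: float = 0.0
    ramp: str = "cosine"

    @property
    def plateau_duration(self) -> float:
        return self.period - self.contraction_duration - self.expansion_duration

    def validate(self) -> None:
        if self.resting_length <= 0:
            raise ParameterError("resting_length must be > 0")
        if not 0 <= self.amplitude < self.resting_length:
            raise ParameterError("amplitude must satisfy 0 <= A < resting_length")
        if self.contraction_duration <= 0 or self.expansion_duration <= 0:
            raise ParameterError("ramp durations must be > 0")
        if self.plateau_duration < 0:
            raise ParameterError("contraction + expansion durations exceed period")
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.ramp not in ("cosine", "linear"):
            raise ParameterError(f"unknown ramp type {self.ramp!r}")


@dataclass(frozen=True)
class TissueGeometry:
    """Geometry and intensity model of the rendered rectangular tissue.

    Defaults approximate a high-aspect-ratio muscle bundle; tests use
    smaller tissues to keep rendering cheap.
    """

    length: float = 308.0          # um, long axis (relaxed)
    width: float = 44.0            # um, short axis
    rotation: float = 0.0          # degrees, long axis from the column axis
    stripe_spacing_relaxed: float = 2.0   # um, z-disc spacing at rest
    stripe_width: float = 0.8      # um, FWHM-ish width of each bright band
    background_level: float = 200.0
    foreground_level: float = 2000.0
    image_shape: tuple[int, int] = (256, 512)   # (rows, cols)
    um_per_px: float = 1.0
    pixel_noise_sd: float = 0.0

    def validate(self) -> None:
        if not self.length > self.width > 0:
            raise ParameterError("require length > width > 0")
        if not self.stripe_spacing_relaxed > self.stripe_width > 0:
            raise ParameterError("require stripe_spacing_relaxed > stripe_width > 0")
        if not self.foreground_level > self.background_level:
            raise ParameterError("require foreground_level > background_level")
        if self.um_per_px <= 0:
            raise ParameterError("um_per_px must be > 0")

    @property
    def n_stripes(self) -> int:
        """Number of rendered stripes: floor(length / spacing) at rest."""
        return int(np.floor(self.length / self.stripe_spacing_relaxed))


@dataclass
class Waveform:
    """A sampled sarcomere-length waveform plus its ground-truth events."""

    t: np.ndarray                 # s
    length: np.ndarray            # um, noisy
    clean: np.ndarray             # um, noiseless
    events: list[dict] = field(default_factory=list)
    params: WaveformParams | None = None


def _cycle_profile(tau: np.ndarray, p: WaveformParams) -> np.ndarray:
    """Noiseless length at phase time tau in [0, period)."""
    L0, A = p.resting_length, p.amplitude
    d_r, d_c, d_e = p.plateau_duration, p.contraction_duration, p.expansion_duration
    out = np.full_like(tau, L0, dtype=float)
    down = (tau >= d_r) & (tau < d_r + d_c)
    up = tau >= d_r + d_c
    td = tau[down] - d_r
    tu = tau[up] - d_r - d_c
    if p.ramp == "cosine":
        out[down] = L0 - 0.5 * A * (1.0 - np.cos(np.pi * td / d_c))
        out[up] = L0 - 0.5 * A * (1.0 + np.cos(np.pi * tu / d_e))
    else:
        out[down] = L0 - A * td / d_c
        out[up] = L0 - A * (1.0 - tu / d_e)
    return out


def generate_length_waveform(params: WaveformParams, seed: int = 0) -> Waveform:
    """Sample the waveform at ``fps`` with ground-truth phase boundaries.

    A trailing plateau of one ``plateau_duration`` is appended after the
    last cycle so that the final relaxation has a well-defined end.
    Ground truth per cycle: relaxed_start (plateau start),
    contraction_onset (plateau end), peak_contraction (descent end) and
    relaxation_end (next plateau start).
    """
    params.validate()
    T = params.period
    duration = params.n_cycles * T + params.plateau_duration
    n = int(np.floor(duration * params.fps)) + 1
    t = np.arange(n) / params.fps

    tau = np.mod(t, T)
    clean = _cycle_profile(tau, params)
    clean[t >= params.n_cycles * T] = params.resting_length  # trailing plateau

    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else clean.copy()

    events = []
    if params.amplitude == 0:  # constant series: no contraction events
        return Waveform(t=t, length=noisy, clean=clean, events=events, params=params)
    for k in range(params.n_cycles):
        c = k * T
        events.append(
            {
                "relaxed_start": c,
                "contraction_onset": c + params.plateau_duration,
                "peak_contraction": c + params.plateau_duration + params.contraction_duration,
                "relaxation_end": c + T,
            }
        )
    return Waveform(t=t, length=noisy, clean=clean, events=events, params=params)


def _tissue_axes(rotation_deg: float) -> tuple[np.ndarray, np.ndarray]:
    th = np.deg2rad(rotation_deg)
    long_axis = np.array([np.sin(th), np.cos(th)])    # (d_row, d_col)
    short_axis = np.array([np.cos(th), -np.sin(th)])
    return long_axis, short_axis


def render_frame(length_um: float, geom: TissueGeometry) -> np.ndarray:
    """Render one noiseless frame (float64) for the given sarcomere length."""
    rows, cols = geom.image_shape
    length_px = geom.length / geom.um_per_px
    width_px = geom.width / geom.um_per_px
    spacing_rest_px = geom.stripe_spacing_relaxed / geom.um_per_px
    spacing_px = length_um / geom.um_per_px
    scale = spacing_px / spacing_rest_px
    half_long = 0.5 * length_px * scale
    half_short = 0.5 * width_px

    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    la, sa = _tissue_axes(geom.rotation)
    # tissue must fit at the relaxed (longest) extent
    half_long_rest = 0.5 * length_px
    corners = [
        np.array([r0, c0]) + s1 * half_long_rest * la + s2 * half_short * sa
        for s1 in (-1, 1)
        for s2 in (-1, 1)
    ]
    for r, c in corners:
        if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
            raise GeometryError("tissue rectangle exceeds image bounds")

    rr, cc = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float), indexing="ij")
    dr, dc = rr - r0, cc - c0
    u = dr * la[0] + dc * la[1]
    v = dr * sa[0] + dc * sa[1]
    inside = (np.abs(u) <= half_long) & (np.abs(v) <= half_short)

    n = geom.n_stripes
    # stripe k center at (k - (n-1)/2) * spacing; nearest-center distance
    w = u / spacing_px + (n - 1) / 2.0
    k = np.clip(np.round(w), 0, n - 1)
    dist = spacing_px * np.abs(w - k)
    sigma = max(geom.stripe_width / geom.um_per_px / 2.0, 1.0)  # >= 1 px: anti-aliasing
    stripe = np.exp(-0.5 * (dist / sigma) ** 2)

    frame = np.full((rows, cols), geom.background_level, dtype=float)
    frame[inside] += (geom.foreground_level - geom.background_level) * stripe[inside]
    return frame


def render_movie(waveform: np.ndarray, geom: TissueGeometry, seed: int = 0) -> np.ndarray:
    """Render a (frames, rows, cols) uint16 stack following the waveform.

    The tissue shortens about its centroid along the long axis as the
    stripe spacing decreases; stripe count is fixed by the relaxed state.
    """
    geom.validate()
    wf = np.asarray(waveform, dtype=float)
    if wf.ndim != 1 or wf.size == 0:
        raise ParameterError("waveform must be a non-empty 1-D array")
    if np.any(wf <= 0):
        raise ParameterError("waveform lengths must all be > 0")

    rng = np.random.default_rng(seed)
    frames = np.empty((wf.size, *geom.image_shape), dtype=np.uint16)
    for i, L in enumerate(wf):
        f = render_frame(float(L), geom)
        if geom.pixel_noise_sd > 0:
            f = f + rng.normal(0.0, geom.pixel_noise_sd, size=f.shape)
        frames[i] = np.clip(f, 0, 65535).astype(np.uint16)
    return frames


def write_movie(path, frames: np.ndarray, waveform: Waveform, geom: TissueGeometry) -> None:
    """Write a multi-page TIFF plus a JSON ground-truth sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, frames)
    sidecar = {
        "t": waveform.t.tolist(),
        "length": waveform.length.tolist(),
        "clean": waveform.clean.tolist(),
        "events": waveform.events,
        "params": asdict(waveform.params) if waveform.params else None,
        "geometry": asdict(geom),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
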