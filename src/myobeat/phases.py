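"""Heuristic contractile-phase detection on a denoised length signal.

The signal is mean-centred; "positive blocks" (runs above the mean)
hold the relaxed plateaus, "negative blocks" the contractions.  Within
each positive block a high-value zone (above a fraction of the block
peak) is scanned inward until the smoothed derivative drops below a
threshold, giving the start and end of the relaxed state; the minimum
of the following negative block is the peak of contraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ParameterError

__all__ = ["PhaseConfig", "ContractionEvent", "smooth_derivative", "detect_phases"]


@dataclass(frozen=True)
class PhaseConfig:
    sg_window: int = 11
    sg_polyorder: int = 3
    high_zone_fraction: float = 0.80
    derivative_threshold: float = 0.1   # um/s

    def validate(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise ParameterError("sg_window must be odd and >= 3")
        if not 0 <= self.sg_polyorder < self.sg_window:
            raise ParameterError("sg_polyorder must be in [0, sg_window)")
        if not 0 < self.high_zone_fraction < 1:
            raise ParameterError("high_zone_fraction must be in (0, 1)")
        if self.derivative_threshold <= 0:
            raise ParameterError("derivative_threshold must be > 0")


@dataclass
class ContractionEvent:
    """One beat: three time points delimiting relaxed / contraction /
    expansion phases.  Index fields are sample indices; times are s."""

    relaxed_start: float
    contraction_onset: float
    peak_contraction: float | None
    relaxation_end: float | None
    relaxed_start_idx: int = 0
    contraction_onset_idx: int = 0
    peak_contraction_idx: int | None = None
    relaxation_end_idx: int | None = None
    complete: bool = False
    threshold_fallback: bool = False


def smooth_derivative(signal: np.ndarray, cfg: PhaseConfig, fps: float) -> np.ndarray:
    """Savitzky-Golay first derivative in um/s."""
    cfg.validate()
    signal = np.asarray(signal, dtype=float)
    if signal.size < cfg.sg_window:
        raise ParameterError("signal shorter than the Savitzky-Golay window")
    if fps <= 0:
        raise ParameterError("fps must be > 0")
    return savgol_filter(signal, cfg.sg_window, cfg.sg_polyorder, deriv=1, delta=1.0 / fps)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def detect_phases(
    signal: np.ndarray, derivative: np.ndarray, cfg: PhaseConfig, fps: float
) -> list[ContractionEvent]:
    """Parse a denoised signal into contraction events.

    Events missing a peak or a relaxation end (signal edges) are
    returned with ``complete=False``; ``threshold_fallback`` marks
    plateau bounds that fell back to the high-zone boundary because the
    derivative never dropped below the threshold.
    """
    cfg.validate()
    y = np.asarray(signal, dtype=float)
    d = np.asarray(derivative, dtype=float)
    if y.shape != d.shape:
        raise ParameterError("signal and derivative must have the same shape")
    x = y - np.mean(y)

    pos = _runs(x > 0)
    neg = _runs(x < 0)
    if not pos or not neg:
        return []

    plateaus = []  # (relaxed_start_idx, onset_idx, fallback)
    for b0, b1 in pos:
        block = x[b0:b1]
        peak = float(block.max())
        zone = np.flatnonzero(block > cfg.high_zone_fraction * peak)
        lb, rb = b0 + int(zone[0]), b0 + int(zone[-1])
        fallback = False
        left = next((i for i in range(lb, rb + 1) if abs(d[i]) < cfg.derivative_threshold), None)
        right = next((i for i in range(rb, lb - 1, -1) if abs(d[i]) < cfg.derivative_threshold), None)
        if left is None or right is None:
            left, right, fallback = lb, rb, True
        plateaus.append((left, right, fallback))

    events = []
    for k, (rs, onset, fb) in enumerate(plateaus):
        peak_idx = None
        for n0, n1 in neg:
            if n0 > onset:
                peak_idx = n0 + int(np.argmin(y[n0:n1]))
                break
        rel_end_idx = plateaus[k + 1][0] if k + 1 < len(plateaus) else None
        complete = (
            peak_idx is not None
            and rel_end_idx is not None
            and rs <= onset < peak_idx < rel_end_idx
        )
        events.append(
            ContractionEvent(
                relaxed_start=rs / fps,
                contraction_onset=onset / fps,
                peak_contraction=None if peak_idx is None else peak_idx / fps,
                relaxation_end=None if rel_end_idx is None else rel_end_idx / fps,
                relaxed_start_idx=rs,
                contraction_onset_idx=onset,
                peak_contraction_idx=peak_idx,
                relaxation_end_idx=rel_end_idx,
                complete=complete,
                threshold_fallback=fb,
            )
        )
    return events
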