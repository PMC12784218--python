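"""Structural and functional metrics per (movie, region), plus paired
drug-effect comparison.

The schema (FEATURE_COLUMNS) has one column per row of the published
metric table; see docs in README for the mapping.  Distributional
relaxed/peak sarcomere-length statistics pool individual sarcomere
lengths over all frames of the corresponding state, while the
shortening amplitude uses the averaged (denoised) signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .denoise import LengthSignal
from .errors import InsufficientPairsError
from .phases import ContractionEvent, PhaseConfig, smooth_derivative
from .segment import TissueMask

__all__ = ["FEATURE_COLUMNS", "extract_features", "paired_comparison", "PairedResult"]

FEATURE_COLUMNS = (
    "number_of_contractions",
    "contraction_period",
    "contraction_frequency",
    "relaxed_sl_mean",
    "relaxed_sl_median",
    "relaxed_sl_p25",
    "relaxed_sl_p75",
    "relaxed_sl_sd",
    "peak_sl_mean",
    "peak_sl_median",
    "peak_sl_p25",
    "peak_sl_p75",
    "peak_sl_sd",
    "shortening_amplitude",
    "peak_shortening_velocity",
    "peak_lengthening_velocity",
    "onset_to_relaxation_end",
    "onset_to_peak",
    "onset_to_half_contracted",
    "half_to_peak",
    "peak_to_relaxation_end",
    "peak_to_half_relaxed",
    "half_relaxed_to_full",
    "tissue_length_relaxed",
    "tissue_length_peak",
    "tissue_width_relaxed",
    "tissue_width_peak",
    "tissue_area_hull_relaxed",
    "tissue_area_hull_peak",
    "tissue_area_rect_relaxed",
    "tissue_area_rect_peak",
    "total_sarcomeres",
    "sarcomere_density_hull",
    "sarcomere_density_rect",
    "noise_level",
)


def _stats_block(values: np.ndarray, prefix: str) -> dict:
    if values.size == 0:
        return {f"{prefix}_{k}": np.nan for k in ("mean", "median", "p25", "p75", "sd")}
    return {
        f"{prefix}_mean": float(np.mean(values)),
        f"{prefix}_median": float(np.median(values)),
        f"{prefix}_p25": float(np.percentile(values, 25)),  # linear interpolation between order stats
        f"{prefix}_p75": float(np.percentile(values, 75)),
        f"{prefix}_sd": float(np.std(values)),
    }


def _crossing_time(y: np.ndarray, i0: int, i1: int, level: float, fps: float) -> float | None:
    """Linearly interpolated first crossing of ``level`` in [i0, i1]."""
    for j in range(i0, i1):
        a, b = y[j], y[j + 1]
        if (a - level) * (b - level) <= 0 and a != b:
            frac = (level - a) / (b - a)
            return (j + frac) / fps
    return None


def extract_features(
    events: list[ContractionEvent],
    signal: LengthSignal,
    masks: list[TissueMask | None],
    detections: pd.DataFrame,
    um_per_px: float,
    phase_cfg: PhaseConfig = PhaseConfig(),
) -> dict:
    """Compute one feature record for a (movie, region) pair.

    ``detections`` is the annotated per-sarcomere table already
    restricted to the signal's region.  ``masks`` is indexed by frame;
    None marks segmentation failures.  Functional fields are NaN when no
    complete event exists; period/frequency need >= 2 complete events.
    """
    rec = {c: np.nan for c in FEATURE_COLUMNS}
    fps = signal.fps
    y = signal.denoised if signal.denoised is not None else signal.raw
    n_frames = len(y)

    complete = [e for e in events if e.complete]
    rec["number_of_contractions"] = len(complete)
    if len(complete) >= 2:
        onsets = np.array([e.contraction_onset for e in complete])
        rec["contraction_period"] = float(np.mean(np.diff(onsets)))
        rec["contraction_frequency"] = 1.0 / rec["contraction_period"]

    # structural: per-frame counts and tissue geometry (all frames)
    counts = detections.groupby("frame").size().reindex(range(n_frames), fill_value=0)
    rec["total_sarcomeres"] = float(counts.mean())
    hull_areas = np.array([m.hull_area for m in masks if m is not None])
    rect_areas = np.array([m.rect_area for m in masks if m is not None])
    if hull_areas.size:
        rec["sarcomere_density_hull"] = rec["total_sarcomeres"] / (hull_areas.mean() * um_per_px**2)
        rec["sarcomere_density_rect"] = rec["total_sarcomeres"] / (rect_areas.mean() * um_per_px**2)
    rec["noise_level"] = signal.noise_level if signal.noise_level is not None else np.nan

    if not complete:
        warnings.warn("no complete contraction event; functional metrics are missing", stacklevel=2)
        return rec

    relaxed_frames = np.concatenate(
        [np.arange(e.relaxed_start_idx, e.contraction_onset_idx + 1) for e in complete]
    )
    peak_frames = np.array([e.peak_contraction_idx for e in complete], dtype=int)

    lengths_by_frame = detections.set_index("frame")["length_um"]
    pooled_relaxed = lengths_by_frame.loc[lengths_by_frame.index.intersection(relaxed_frames)].to_numpy()
    pooled_peak = lengths_by_frame.loc[lengths_by_frame.index.intersection(peak_frames)].to_numpy()
    rec.update(_stats_block(pooled_relaxed, "relaxed_sl"))
    rec.update(_stats_block(pooled_peak, "peak_sl"))

    # amplitude from the averaged signal ("average sarcomere lengths")
    rec["shortening_amplitude"] = float(np.mean(y[relaxed_frames]) - np.mean(y[peak_frames]))

    deriv = smooth_derivative(y, phase_cfg, fps)
    sv, lv = [], []
    for e in complete:
        sv.append(np.max(np.abs(deriv[e.contraction_onset_idx : e.peak_contraction_idx + 1])))
        lv.append(np.max(np.abs(deriv[e.peak_contraction_idx : e.relaxation_end_idx + 1])))
    rec["peak_shortening_velocity"] = float(np.max(sv))
    rec["peak_lengthening_velocity"] = float(np.max(lv))

    timings = {k: [] for k in (
        "onset_to_relaxation_end", "onset_to_peak", "onset_to_half_contracted",
        "half_to_peak", "peak_to_relaxation_end", "peak_to_half_relaxed",
        "half_relaxed_to_full",
    )}
    for e in complete:
        o, p, r = e.contraction_onset_idx, e.peak_contraction_idx, e.relaxation_end_idx
        t_o, t_p, t_r = e.contraction_onset, e.peak_contraction, e.relaxation_end
        timings["onset_to_relaxation_end"].append(t_r - t_o)
        timings["onset_to_peak"].append(t_p - t_o)
        timings["peak_to_relaxation_end"].append(t_r - t_p)
        half_c = 0.5 * (y[o] + y[p])
        tc = _crossing_time(y, o, p, half_c, fps)
        if tc is not None:
            timings["onset_to_half_contracted"].append(tc - t_o)
            timings["half_to_peak"].append(t_p - tc)
        half_r = 0.5 * (y[p] + y[r])
        tr_ = _crossing_time(y, p, r, half_r, fps)
        if tr_ is not None:
            timings["peak_to_half_relaxed"].append(tr_ - t_p)
            timings["half_relaxed_to_full"].append(t_r - tr_)
    for k, vals in timings.items():
        rec[k] = float(np.mean(vals)) if vals else np.nan

    # tissue geometry: median over relaxed-phase frames, mean over peak frames
    def _geo(frames, reducer):
        ms = [masks[f] for f in frames if f < len(masks) and masks[f] is not None]
        if not ms:
            return dict.fromkeys(("len", "wid", "hull", "rect"), np.nan)
        return {
            "len": reducer([m.rect_dims[0] for m in ms]) * um_per_px,
            "wid": reducer([m.rect_dims[1] for m in ms]) * um_per_px,
            "hull": reducer([m.hull_area for m in ms]) * um_per_px**2,
            "rect": reducer([m.rect_area for m in ms]) * um_per_px**2,
        }

    g_rel = _geo(relaxed_frames, np.median)
    g_peak = _geo(peak_frames, np.mean)
    rec["tissue_length_relaxed"] = g_rel["len"]
    rec["tissue_width_relaxed"] = g_rel["wid"]
    rec["tissue_area_hull_relaxed"] = g_rel["hull"]
    rec["tissue_area_rect_relaxed"] = g_rel["rect"]
    rec["tissue_length_peak"] = g_peak["len"]
    rec["tissue_width_peak"] = g_peak["wid"]
    rec["tissue_area_hull_peak"] = g_peak["hull"]
    rec["tissue_area_rect_peak"] = g_peak["rect"]
    return rec


@dataclass(frozen=True)
class PairedResult:
    delta_pct: float
    t_statistic: float
    p_value: float
    n: int


def paired_comparison(baseline, treated) -> PairedResult:
    """Percent change of the mean and a two-sided paired t-test.

    Pairs with a missing value on either side are dropped; ``n`` is the
    number of retained pairs.
    """
    b = np.asarray(baseline, dtype=float)
    t = np.asarray(treated, dtype=float)
    if b.shape != t.shape:
        raise InsufficientPairsError("baseline and treated must be equal-length")
    keep = np.isfinite(b) & np.isfinite(t)
    b, t = b[keep], t[keep]
    if b.size < 2:
        raise InsufficientPairsError(f"need >= 2 complete pairs, got {b.size}")
    delta_pct = 100.0 * (np.mean(t) - np.mean(b)) / np.mean(b)
    diffs = t - b
    if np.std(diffs) <= 1e-10 * (abs(float(np.mean(diffs))) + 1e-30):
        warnings.warn("zero-variance differences; p-value undefined", stacklevel=2)
        return PairedResult(float(delta_pct), np.nan, np.nan, int(b.size))
    res = stats.ttest_rel(t, b)
    return PairedResult(float(delta_pct), float(res.statistic), float(res.pvalue), int(b.size))
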