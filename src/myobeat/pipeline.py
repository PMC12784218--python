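"""End-to-end orchestration: movie -> detections -> masks -> regions ->
signals -> events -> features, with QC, config round-trip and outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .denoise import KernelConfig, LengthSignal, average_length_signal, gpr_denoise
from .detect import DetectConfig, detect_zdiscs, link_sarcomeres
from .errors import EmptyRegionError, InputError, ParameterError, SegmentationFailure
from .features import FEATURE_COLUMNS, extract_features
from .partition import REGION_SELECTORS, assign_regions
from .phases import ContractionEvent, PhaseConfig, detect_phases, smooth_derivative
from .segment import SegmentConfig, TissueMask, segment_tissue

__all__ = ["PipelineConfig", "QCReport", "PipelineResult", "load_movie", "run_pipeline", "qc_check"]

logger = logging.getLogger("myobeat")

_REGION_GROUPS = {
    "whole": ("whole",),
    "thirds": ("left", "center", "right"),
    "halves": ("top", "bottom"),
    "sixths": tuple(f"{lo}-{tr}" for lo in ("left", "center", "right") for tr in ("top", "bottom")),
}


@dataclass
class PipelineConfig:
    um_per_px: float = 1.0
    fps: float = 100.0
    regions: tuple[str, ...] = ("whole", "thirds")
    detect: DetectConfig = field(default_factory=DetectConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    max_zdiscs_per_frame: int = 1500
    max_count_cv: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.um_per_px <= 0:
            raise ParameterError("um_per_px must be > 0")
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        for r in self.regions:
            if r not in _REGION_GROUPS and r not in REGION_SELECTORS:
                raise ParameterError(f"unknown region selection {r!r}")

    def region_selectors(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.regions:
            for sel in _REGION_GROUPS.get(r, (r,)):
                if sel not in out:
                    out.append(sel)
        return tuple(out)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = list(self.regions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("detect", DetectConfig), ("segment", SegmentConfig),
                         ("kernel", KernelConfig), ("phase", PhaseConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "segment" and "noise_patch" in sub:
                    sub["noise_patch"] = tuple(sub["noise_patch"])
                d[key] = typ(**sub)
        if "regions" in d:
            d["regions"] = tuple(d["regions"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class QCReport:
    zdisc_counts: list[int]
    n_segmentation_failures: int
    n_frames: int
    flags: dict[str, bool]
    excluded: bool
    reasons: list[str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    features: pd.DataFrame            # one row per region
    signals: dict[str, LengthSignal]
    events: dict[str, list[ContractionEvent]]
    masks: list[TissueMask | None]
    detections: pd.DataFrame          # annotated sarcomere table
    qc: QCReport
    config: PipelineConfig


def qc_check(zdisc_counts, n_segmentation_failures: int, n_frames: int, config: PipelineConfig) -> QCReport:
    """Post-hoc quality control mirroring the known z-disc-flood failure
    mode: a movie is excluded when any frame floods with detections,
    counts are grossly unstable, or segmentation fails on > 10% of frames."""
    counts = np.asarray(list(zdisc_counts), dtype=float)
    if n_frames < 1:
        raise ParameterError("need at least one processed frame")
    flags = {"zdisc_flood": False, "count_instability": False, "segmentation_failures": False}
    reasons = []
    if counts.size and counts.max() > config.max_zdiscs_per_frame:
        flags["zdisc_flood"] = True
        reasons.append(
            f"z-disc flood: max per-frame count {int(counts.max())} > {config.max_zdiscs_per_frame}"
        )
    if counts.size and counts.mean() > 0:
        cv = counts.std() / counts.mean()
        if cv > config.max_count_cv:
            flags["count_instability"] = True
            reasons.append(f"z-disc count CV {cv:.2f} > {config.max_count_cv}")
    if n_segmentation_failures > 0.1 * n_frames:
        flags["segmentation_failures"] = True
        reasons.append(f"segmentation failed on {n_segmentation_failures}/{n_frames} frames")
    excluded = any(flags.values())
    return QCReport(
        zdisc_counts=[int(c) for c in counts],
        n_segmentation_failures=n_segmentation_failures,
        n_frames=n_frames,
        flags=flags,
        excluded=excluded,
        reasons=reasons,
    )


def load_movie(path) -> np.ndarray:
    """Load a multi-page TIFF or a lexicographically ordered image directory."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"movie path does not exist: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise InputError(f"no frame images in directory {path}")
        import imageio.v3 as iio

        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    else:
        frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise InputError(f"expected a (frames, rows, cols) stack, got shape {frames.shape}")
    return frames


def _detect_all(frames: np.ndarray, config: PipelineConfig):
    """Per-frame segmentation, detection and region labelling.

    Frames are independent; sequential execution is used for
    determinism but results would be identical in any order.
    """
    masks: list[TissueMask | None] = []
    rows = []
    counts = []
    n_seg_fail = 0
    for i, frame in enumerate(frames):
        try:
            mask = segment_tissue(frame, config.segment, frame_index=i)
        except SegmentationFailure:
            mask = None
            n_seg_fail += 1
        masks.append(mask)
        discs = detect_zdiscs(frame, config.detect, frame_index=i)
        counts.append(len(discs))
        if len(discs) > config.max_zdiscs_per_frame:
            continue  # flood frame: skip pairing, QC will flag it
        sarcs = link_sarcomeres(discs, config.detect, config.um_per_px)
        if mask is None:
            continue
        labelled, _ = assign_regions(sarcs, mask)
        for s, lab in labelled:
            rows.append(
                {
                    "frame": i,
                    "row": s.midpoint[0],
                    "col": s.midpoint[1],
                    "length_um": s.length,
                    "axis_angle": s.axis_angle,
                    "longitudinal": lab.longitudinal,
                    "transverse": lab.transverse,
                }
            )
    detections = pd.DataFrame(
        rows, columns=["frame", "row", "col", "length_um", "axis_angle", "longitudinal", "transverse"]
    )
    return masks, detections, counts, n_seg_fail


def run_pipeline(movie_path, config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run all stages on one movie; optionally write outputs to ``out_dir``."""
    config.validate()
    frames = load_movie(movie_path)
    n_frames = frames.shape[0]

    masks, detections, counts, n_seg_fail = _detect_all(frames, config)
    qc = qc_check(counts, n_seg_fail, n_frames, config)
    if n_seg_fail == n_frames:
        if out_dir is not None:
            _write_qc(Path(out_dir), qc)
        raise SegmentationFailure(-1, "segmentation failed on every frame")

    signals: dict[str, LengthSignal] = {}
    events: dict[str, list[ContractionEvent]] = {}
    feature_rows = []
    for region in config.region_selectors():
        try:
            sig = average_length_signal(detections, region, config.fps, n_frames=n_frames)
        except EmptyRegionError:
            logger.warning("region %s empty in all frames; skipped", region)
            continue
        sig = gpr_denoise(sig, config.kernel)
        deriv = smooth_derivative(sig.denoised, config.phase, config.fps)
        evs = detect_phases(sig.denoised, deriv, config.phase, config.fps)
        if region == "whole":
            region_det = detections
        elif region in ("left", "center", "right"):
            region_det = detections[detections["longitudinal"] == region]
        elif region in ("top", "bottom"):
            region_det = detections[detections["transverse"] == region]
        else:
            lo, tr = region.split("-", 1)
            region_det = detections[
                (detections["longitudinal"] == lo) & (detections["transverse"] == tr)
            ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = extract_features(evs, sig, masks, region_det, config.um_per_px, config.phase)
        rec["region"] = region
        feature_rows.append(rec)
        signals[region] = sig
        events[region] = evs

    features = pd.DataFrame(feature_rows, columns=["region", *FEATURE_COLUMNS])
    result = PipelineResult(
        features=features,
        signals=signals,
        events=events,
        masks=masks,
        detections=detections,
        qc=qc,
        config=config,
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), result)
    return result


def _write_qc(out: Path, qc: QCReport) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "qc.json").write_text(json.dumps(qc.to_dict(), indent=2))


def _write_outputs(out: Path, res: PipelineResult) -> None:
    out.mkdir(parents=True, exist_ok=True)
    res.detections.to_csv(out / "detections.csv", index=False)
    geo = pd.DataFrame(
        [
            {
                "frame": m.frame_index,
                "center_row": m.rect_center[0],
                "center_col": m.rect_center[1],
                "long_px": m.rect_dims[0],
                "short_px": m.rect_dims[1],
                "angle_deg": m.rect_angle,
                "hull_area_px2": m.hull_area,
                "rect_area_px2": m.rect_area,
            }
            for m in res.masks
            if m is not None
        ]
    )
    geo.to_csv(out / "geometry.csv", index=False)
    sig_dir = out / "signals"
    sig_dir.mkdir(exist_ok=True)
    for region, sig in res.signals.items():
        pd.DataFrame(
            {"frame": np.arange(len(sig.t)), "t_s": sig.t, "raw_um": sig.raw, "denoised_um": sig.denoised}
        ).to_csv(sig_dir / f"{region}.csv", index=False)
    ev_rows = [
        {
            "region": region,
            "event": k,
            "relaxed_start_s": e.relaxed_start,
            "contraction_onset_s": e.contraction_onset,
            "peak_contraction_s": e.peak_contraction,
            "relaxation_end_s": e.relaxation_end,
            "complete": e.complete,
        }
        for region, evs in res.events.items()
        for k, e in enumerate(evs)
    ]
    pd.DataFrame(
        ev_rows,
        columns=[
            "region", "event", "relaxed_start_s", "contraction_onset_s",
            "peak_contraction_s", "relaxation_end_s", "complete",
        ],
    ).to_csv(out / "events.csv", index=False)
    res.features.to_csv(out / "features.csv", index=False)
    _write_qc(out, res.qc)
    cfg = res.config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    (out / "run.log").write_text(
        f"myobeat {__version__}\nconfig_sha256 {cfg_hash}\nseed {res.config.seed}\n"
        f"frames {res.qc.n_frames}\nexcluded {res.qc.excluded}\n"
    )
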