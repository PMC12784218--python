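"""Shared fixtures: compact synthetic movies generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from myobeat.pipeline import PipelineConfig, run_pipeline
from myobeat.synth import TissueGeometry, WaveformParams, generate_length_waveform, render_movie, write_movie


def small_geometry(**overrides) -> TissueGeometry:
    """A compact tissue that keeps rendering and detection cheap."""
    kw = dict(
        length=60.0,
        width=12.0,
        stripe_spacing_relaxed=2.0,
        stripe_width=0.8,
        background_level=200.0,
        foreground_level=2000.0,
        image_shape=(128, 384),
        um_per_px=0.2,
        pixel_noise_sd=20.0,
        rotation=10.0,
    )
    kw.update(overrides)
    return TissueGeometry(**kw)


@pytest.fixture(scope="session")
def default_params() -> WaveformParams:
    return WaveformParams(
        resting_length=2.0,
        amplitude=0.4,
        period=1.0,
        contraction_duration=0.2,
        expansion_duration=0.3,
        n_cycles=5,
        fps=100.0,
        noise_sd=0.005,
    )


@pytest.fixture(scope="session")
def small_movie(tmp_path_factory, default_params):
    """A rendered 5-cycle movie on disk with its ground truth."""
    geom = small_geometry()
    wf = generate_length_waveform(default_params, seed=11)
    frames = render_movie(wf.length, geom, seed=12)
    path = tmp_path_factory.mktemp("movie") / "movie.tiff"
    write_movie(path, frames, wf, geom)
    return {"path": path, "frames": frames, "waveform": wf, "geometry": geom}


@pytest.fixture(scope="session")
def small_movie_result(small_movie):
    """Pipeline output on the shared movie (whole tissue + thirds)."""
    cfg = PipelineConfig(um_per_px=0.2, fps=100.0, regions=("whole", "thirds"), seed=0)
    return run_pipeline(small_movie["path"], cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
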