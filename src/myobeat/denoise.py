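"""Regional average-sarcomere-length signals and Gaussian-process denoising.

The GP uses a sum kernel of Periodic + RBF + Matern(nu=2.5) components
plus an observation-noise term.  Hyperparameters are fitted by
maximizing the marginal likelihood; the period is initialized from the
dominant FFT peak of the mean-centred raw signal, which makes the fit
robust and reproducible without restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    ExpSineSquared,
    Matern,
    WhiteKernel,
)

from .errors import EmptyRegionError, ParameterError

__all__ = ["LengthSignal", "KernelConfig", "average_length_signal", "gpr_denoise"]


@dataclass
class LengthSignal:
    """A per-region average-sarcomere-length time series.

    ``raw`` may contain NaN for frames with no sarcomere in the region;
    ``denoised`` and ``noise_level`` are filled by :func:`gpr_denoise`.
    """

    region: str
    t: np.ndarray                       # s
    raw: np.ndarray                     # um, NaN = missing
    fps: float
    denoised: np.ndarray | None = None  # um
    noise_level: float | None = None    # um, sd(raw - denoised)
    hyperparameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class KernelConfig:
    """Sum-kernel GP configuration.  ``composition`` may be "sum" or
    "product"; the Matern smoothness is fixed at 2.5."""

    composition: str = "sum"
    period_init: float | None = None    # s; None = FFT-initialized
    max_iter: int = 300
    learning_rate: float = 0.1          # unused by L-BFGS; kept for config round-trip
    tol: float = 1e-5
    seed: int = 0

    def validate(self) -> None:
        if self.composition not in ("sum", "product"):
            raise ParameterError("composition must be 'sum' or 'product'")
        if self.max_iter < 1 or self.tol <= 0:
            raise ParameterError("max_iter >= 1 and tol > 0 required")


def average_length_signal(
    detections: pd.DataFrame, region: str, fps: float, n_frames: int | None = None
) -> LengthSignal:
    """Unweighted per-frame mean sarcomere length for one region.

    ``detections`` needs columns frame, length_um, longitudinal,
    transverse (the annotated per-sarcomere table).  Frames with no
    sarcomere in the region are NaN.
    """
    if fps <= 0:
        raise ParameterError("fps must be > 0")
    required = {"frame", "length_um", "longitudinal", "transverse"}
    if not required.issubset(detections.columns):
        raise ParameterError(f"detections table must have columns {sorted(required)}")

    if region == "whole":
        sub = detections
    elif region in ("left", "center", "right"):
        sub = detections[detections["longitudinal"] == region]
    elif region in ("top", "bottom"):
        sub = detections[detections["transverse"] == region]
    elif "-" in region:
        lo, tr = region.split("-", 1)
        sub = detections[(detections["longitudinal"] == lo) & (detections["transverse"] == tr)]
    else:
        raise ParameterError(f"unknown region selector {region!r}")

    if n_frames is None:
        n_frames = int(detections["frame"].max()) + 1 if len(detections) else 0
    raw = np.full(n_frames, np.nan)
    if len(sub):
        means = sub.groupby("frame")["length_um"].mean()
        idx = means.index.to_numpy(dtype=int)
        raw[idx[idx < n_frames]] = means.to_numpy()[idx < n_frames]
    if not np.any(np.isfinite(raw)):
        raise EmptyRegionError(f"region {region!r} is empty in all frames")
    t = np.arange(n_frames) / fps
    return LengthSignal(region=region, t=t, raw=raw, fps=fps)


def _fft_period(t: np.ndarray, y: np.ndarray) -> float:
    """Period of the dominant non-DC FFT peak of the mean-centred signal."""
    dt = float(np.median(np.diff(t)))
    yc = y - np.mean(y)
    spec = np.abs(np.fft.rfft(yc))
    freqs = np.fft.rfftfreq(y.size, d=dt)
    if spec.size < 2:
        return max(t[-1] - t[0], dt)
    k = 1 + int(np.argmax(spec[1:]))
    if freqs[k] <= 0:
        return max(t[-1] - t[0], dt)
    return float(1.0 / freqs[k])


def gpr_denoise(signal: LengthSignal, cfg: KernelConfig = KernelConfig()) -> LengthSignal:
    """Fit the composite-kernel GP and fill ``denoised`` / ``noise_level``.

    Missing frames are excluded from training and filled by the
    posterior mean.  Deterministic for a fixed config.
    """
    cfg.validate()
    t, raw = signal.t, signal.raw
    mask = np.isfinite(raw)
    n_obs = int(mask.sum())
    if n_obs < 50:
        raise ParameterError(f"need >= 50 non-missing samples, got {n_obs}")

    y = raw[mask]
    y_mean, y_sd = float(np.mean(y)), float(np.std(y))
    if y_sd < 1e-12:  # degenerate constant input
        out = LengthSignal(signal.region, t, raw, signal.fps)
        out.denoised = np.full_like(t, y_mean, dtype=float)
        out.noise_level = 0.0
        out.hyperparameters = {"constant": y_mean}
        return out

    ts = t[mask]
    ys = (y - y_mean) / y_sd

    p0 = cfg.period_init or _fft_period(ts, ys)
    ls0 = p0 / 4.0
    k_per = ConstantKernel(1.0 / 3.0, (1e-4, 1e3)) * ExpSineSquared(
        length_scale=1.0,
        periodicity=p0,
        length_scale_bounds=(1e-2, 1e3),
        periodicity_bounds=(p0 / 3.0, p0 * 3.0),
    )
    k_rbf = ConstantKernel(1.0 / 3.0, (1e-4, 1e3)) * RBF(ls0, (1e-3 * p0, 1e3 * p0))
    k_mat = ConstantKernel(1.0 / 3.0, (1e-4, 1e3)) * Matern(ls0, (1e-3 * p0, 1e3 * p0), nu=2.5)
    if cfg.composition == "sum":
        kernel = k_per + k_rbf + k_mat
    else:
        kernel = k_per * k_rbf * k_mat
    kernel = kernel + WhiteKernel(0.1, (1e-8, 1e1))

    def optimizer(obj_func, initial_theta, bounds):
        res = minimize(
            obj_func,
            initial_theta,
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": cfg.max_iter, "ftol": cfg.tol},
        )
        if not res.success:
            warnings.warn(
                f"GP hyperparameter optimization did not converge: {res.message}",
                RuntimeWarning,
                stacklevel=2,
            )
        return res.x, res.fun

    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-10,
        optimizer=optimizer,
        normalize_y=False,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(ts.reshape(-1, 1), ys)
    mean = gp.predict(t.reshape(-1, 1))

    out = LengthSignal(signal.region, t, raw, signal.fps)
    out.denoised = mean * y_sd + y_mean
    out.noise_level = float(np.std(raw[mask] - out.denoised[mask]))
    fitted = gp.kernel_
    out.hyperparameters = {
        "kernel": str(fitted),
        "periodicity": _extract_periodicity(fitted),
        "log_marginal_likelihood": float(gp.log_marginal_likelihood_value_),
    }
    return out


def _extract_periodicity(kernel) -> float | None:
    for name, value in kernel.get_params().items():
        if name.endswith("periodicity"):
            return float(value)
    return None
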