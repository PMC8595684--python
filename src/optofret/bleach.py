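"""Diffusing photobleached-sensor pool: model, fitting, and ratio correction.

A focused stimulation pulse photobleaches a small pool of membrane sensor
at the target site.  The bleached molecules diffuse laterally and, because
the two fluorophores bleach asymmetrically, transiently bias the local
acceptor/donor ratio.  The pool is modelled as a radial Gaussian dip that
spreads by free two-dimensional diffusion:

    b(r, t) = b0 * s0^2 / s^2(t) * exp(-r^2 / (2 s^2(t))),
    s^2(t) = s0^2 + 2 D t

which conserves the total bleached amount.  The observed ratio is biased
by the factor (1 - alpha * b), where alpha is the channel-asymmetry
coefficient (alpha = 0: both channels bleach equally, ratio unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class BleachModel:
    """Gaussian bleach dip spreading by free 2-D diffusion.

    Parameters are expressed at the calibration stimulation power; an
    experiment at a different power scales the amplitude linearly
    (``power / calibration_power``).
    """

    b0: float  # initial bleached fraction at the dip centre, in [0, 1]
    sigma0: float  # initial Gaussian width, µm
    center: tuple[float, float]  # (row, col) pixel coordinate of the dip
    pixel_size: float  # µm per pixel of the fitted image grid
    diffusion: float = 0.5  # µm²/s
    alpha: float = 1.0  # channel-asymmetry coefficient of the ratio bias
    calibration_power: float = 37.0  # µW of the calibration pulse

    def __post_init__(self) -> None:
        if not (0.0 <= self.b0 <= 1.0):
            raise ValueError("b0 must lie in [0, 1]")
        if self.b0 > 0 and self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.diffusion < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center"] = list(self.center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BleachModel":
        d = dict(d)
        d["center"] = tuple(d["center"])
        return cls(**d)


def _radii_um(shape: tuple[int, int], center: tuple[float, float],
              pixel_size: float) -> np.ndarray:
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return pixel_size * np.hypot(rows, cols)


def propagate_bleach(model: BleachModel, t: float,
                     shape: tuple[int, int],
                     power: float | None = None) -> np.ndarray:
    """Bleach-fraction image b(x, t) on the pixel grid at time t >= 0.

    ``power`` scales the amplitude linearly against the model's
    calibration power; ``None`` means the calibration power itself.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    scale = 1.0 if power is None else power / model.calibration_power
    if model.b0 == 0 or scale == 0:
        return np.zeros(shape)
    s2 = model.sigma0 ** 2 + 2.0 * model.diffusion * t
    amp = model.b0 * scale * model.sigma0 ** 2 / s2
    r = _radii_um(shape, model.center, model.pixel_size)
    return amp * np.exp(-(r ** 2) / (2.0 * s2))


def _dip(r_um: np.ndarray, b0: float, sigma0: float) -> np.ndarray:
    return 1.0 - b0 * np.exp(-(r_um ** 2) / (2.0 * sigma0 ** 2))


def fit_bleach_profile(post_bleach: np.ndarray, pre_bleach: np.ndarray,
                       center: tuple[float, float], pixel_size: float,
                       calibration_power: float = 37.0,
                       diffusion: float = 0.5,
                       alpha: float = 1.0) -> BleachModel:
    """Fit the initial bleach amplitude and width from a pre/post image pair.

    Fits ``1 - b0 * exp(-r^2 / (2 sigma0^2))`` to the per-pixel
    post/pre intensity ratio by least squares.  A non-dip fit
    (b0 <= 0) returns a zero-bleach model.
    """
    post = np.asarray(post_bleach, dtype=float)
    pre = np.asarray(pre_bleach, dtype=float)
    if post.shape != pre.shape:
        raise ValueError("pre/post images must share a shape")
    ok = pre > 0
    if not ok.any():
        raise ValueError("pre-bleach image has no positive pixels")
    r = _radii_um(post.shape, center, pixel_size)
    ratio = np.where(ok, post / np.where(ok, pre, 1.0), 1.0)
    guess_b0 = float(np.clip(1.0 - ratio[ok].min(), 0.05, 0.95))
    try:
        popt, _ = curve_fit(_dip, r[ok].ravel(), ratio[ok].ravel(),
                            p0=[guess_b0, 2.0],
                            bounds=([-1.0, 1e-3], [1.0, 100.0]))
        b0, sigma0 = float(popt[0]), float(popt[1])
    except RuntimeError:
        b0, sigma0 = 0.0, 1.0
    if b0 <= 1e-6:  # non-dip: return the zero-bleach model
        b0, sigma0 = 0.0, 1.0
    return BleachModel(b0=min(b0, 1.0), sigma0=sigma0, center=center,
                       pixel_size=pixel_size, diffusion=diffusion,
                       alpha=alpha, calibration_power=calibration_power)


def fit_recovery_series(images: Sequence[np.ndarray], pre_bleach: np.ndarray,
                        center: tuple[float, float], times: Sequence[float],
                        pixel_size: float,
                        calibration_power: float = 37.0,
                        alpha: float = 1.0) -> BleachModel:
    """Jointly fit (b0, sigma0, D) to a post-bleach recovery image series.

    ``images[i]`` is the intensity image at ``times[i]`` seconds after the
    bleach pulse; each is divided by ``pre_bleach`` and the diffusing-dip
    model is fit to all frames at once by least squares.
    """
    pre = np.asarray(pre_bleach, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(images) != times.size:
        raise ValueError("one timestamp per image required")
    r = _radii_um(pre.shape, center, pixel_size)
    ok = pre > 0
    r2s, ts, ys = [], [], []
    for img, t in zip(images, times):
        img = np.asarray(img, dtype=float)
        r2s.append((r[ok] ** 2).ravel())
        ts.append(np.full(ok.sum(), t))
        ys.append((img[ok] / pre[ok]).ravel())
    r2 = np.concatenate(r2s)
    tt = np.concatenate(ts)
    y = np.concatenate(ys)

    def model_fn(x, b0, sigma0, D):
        r2_, t_ = x
        s2 = sigma0 ** 2 + 2.0 * D * t_
        return 1.0 - b0 * (sigma0 ** 2 / s2) * np.exp(-r2_ / (2.0 * s2))

    popt, _ = curve_fit(model_fn, (r2, tt), y, p0=[0.2, 2.0, 0.3],
                        bounds=([1e-4, 1e-2, 1e-4], [1.0, 50.0, 50.0]))
    b0, sigma0, D = (float(v) for v in popt)
    return BleachModel(b0=b0, sigma0=sigma0, center=center,
                       pixel_size=pixel_size, diffusion=D, alpha=alpha,
                       calibration_power=calibration_power)


@dataclass
class BleachField:
    """Total bleach fraction from a log of focal pulses.

    Sums per-pulse diffusing-Gaussian contributions and clips at the
    physical bound b <= 1.  ``pulses`` is a list of ``(time_s, power)``
    pairs on the model's power scale.
    """

    model: BleachModel
    pulses: list[tuple[float, float]] = field(default_factory=list)

    def fraction(self, t: float, shape: tuple[int, int]) -> np.ndarray:
        b = np.zeros(shape)
        for t_stim, power in self.pulses:
            if t >= t_stim:
                b += propagate_bleach(self.model, t - t_stim, shape,
                                      power=power)
        return np.clip(b, 0.0, 1.0)

    @property
    def alpha(self) -> float:
        return self.model.alpha


def correct_ratio_series(frames: Sequence[np.ndarray], model: BleachModel,
                         stim_log: Sequence[tuple[float, float]],
                         times: Sequence[float]) -> list[np.ndarray]:
    """Divide each post-stimulus ratio frame by its bleach bias (1 - alpha*b).

    ``stim_log`` holds ``(time_s, power)`` per pulse; ``times[i]`` is the
    acquisition time of ``frames[i]``.  Contributions from multiple pulses
    are summed and clipped at b <= 1.  NaN (invalid) pixels pass through.
    """
    fieldm = BleachField(model, list(stim_log))
    out = []
    for frame, t in zip(frames, times):
        frame = np.asarray(frame, dtype=float)
        b = fieldm.fraction(t, frame.shape)
        f = 1.0 - model.alpha * b
        if np.any(f <= 0):
            raise ValueError("bleach correction factor <= 0; "
                             "mis-scaled bleach model")
        out.append(frame / f)
    return out
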