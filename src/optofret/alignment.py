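"""Donor->acceptor camera registration by correlation maximization.

The two cameras view the same field through different optical paths, so
their coordinate systems differ by a translation, an independent stretch
along each axis, and small second-order aberration terms.  The mapping
from output (acceptor) pixel coordinates to the donor sampling position
is a 12-coefficient polynomial, fit by maximizing the Pearson correlation
between gradient-magnitude feature images in a coarse-to-fine staged
derivative-free search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import minimize
from skimage.measure import block_reduce


class RegistrationError(ValueError):
    """Raised when alignment fitting fails to reach the correlation floor."""


# Coefficient layout, per output axis, on [-1, 1]-normalized coordinates:
#   [const, x, y, x^2, y^2, x*y]   (x = column axis, y = row axis)
_IDENTITY_X = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
_IDENTITY_Y = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])


@dataclass
class AlignmentModel:
    """Polynomial map from acceptor-grid coordinates to donor sampling
    coordinates.

    ``coefficients`` is a 12-vector: the first six give the donor x
    (column) coordinate, the last six the donor y (row) coordinate, each
    as [const, x, y, x^2, y^2, x*y] on coordinates normalized to [-1, 1]
    per axis.  Pixel convention: 0-based indices, pixel centers at
    integers, row = y, column = x, origin top-left.
    """

    coefficients: np.ndarray
    reference_shape: tuple[int, int]
    fit_quality: float = 1.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (12,):
            raise ValueError("expected 12 coefficients")
        if not -1.0 <= self.fit_quality <= 1.0:
            raise ValueError("fit_quality must be a correlation in [-1, 1]")

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "AlignmentModel":
        return cls(np.concatenate([_IDENTITY_X, _IDENTITY_Y]), tuple(shape))

    @classmethod
    def translation(cls, shape: tuple[int, int], dx_px: float,
                    dy_px: float) -> "AlignmentModel":
        """Pure shift: sampling position = output position + (dx, dy) px."""
        m = cls.identity(shape)
        sy, sx = _half_spans(shape)
        m.coefficients[0] = dx_px / sx
        m.coefficients[6] = dy_px / sy
        return m

    # -- geometry -----------------------------------------------------
    def map_coords(self, rows: np.ndarray, cols: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Donor (row, col) sampling coordinates for output pixels."""
        sy, sx = _half_spans(self.reference_shape)
        u = (np.asarray(cols, dtype=float) - sx) / sx
        v = (np.asarray(rows, dtype=float) - sy) / sy
        basis = [np.ones_like(u), u, v, u * u, v * v, u * v]
        cx = self.coefficients[:6]
        cy = self.coefficients[6:]
        xs = sum(c * b for c, b in zip(cx, basis))
        ys = sum(c * b for c, b in zip(cy, basis))
        return ys * sy + sy, xs * sx + sx

    def translation_px(self) -> tuple[float, float]:
        """(dx, dy) displacement of the field centre, in pixels."""
        sy, sx = _half_spans(self.reference_shape)
        return float(self.coefficients[0] * sx), float(self.coefficients[6] * sy)

    def is_invertible(self) -> bool:
        """Jacobian determinant > 0 at the four corners and the centre."""
        cx, cy = self.coefficients[:6], self.coefficients[6:]
        for u, v in [(-1, -1), (-1, 1), (1, -1), (1, 1), (0, 0)]:
            dxu = cx[1] + 2 * cx[3] * u + cx[5] * v
            dxv = cx[2] + 2 * cx[4] * v + cx[5] * u
            dyu = cy[1] + 2 * cy[3] * u + cy[5] * v
            dyv = cy[2] + 2 * cy[4] * v + cy[5] * u
            if dxu * dyv - dxv * dyu <= 0:
                return False
        return True

    # -- persistence --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "reference_shape": list(self.reference_shape),
            "fit_quality": self.fit_quality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentModel":
        return cls(np.asarray(d["coefficients"]),
                   tuple(d["reference_shape"]), d.get("fit_quality", 1.0))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "AlignmentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _half_spans(shape: tuple[int, int]) -> tuple[float, float]:
    return (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0


def preprocess_for_alignment(image: np.ndarray, *,
                             bg_percentile: float = 1.5,
                             sigma: float = 2.0) -> np.ndarray:
    """Background-subtract, normalize, smooth, and take the gradient
    magnitude, emphasizing object edges for correlation fitting.

    A constant image yields an all-zero feature image (flagged by the
    caller's correlation floor, not fatal here).
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    img = img - np.percentile(img, bg_percentile)
    np.clip(img, 0.0, None, out=img)
    peak = img.max()
    if peak > 0:
        img /= peak
    img = gaussian_filter(img, sigma, mode="reflect")
    gy, gx = np.gradient(img)
    return np.hypot(gx, gy)


def _warp(image: np.ndarray, model: AlignmentModel) -> np.ndarray:
    rows, cols = np.indices(model.reference_shape)
    src_r, src_c = model.map_coords(rows, cols)
    return map_coordinates(image, [src_r, src_c], order=1, mode="nearest")


def _pearson(a: np.ndarray, b: np.ndarray, margin: int) -> float:
    if margin > 0:
        a = a[margin:-margin, margin:-margin]
        b = b[margin:-margin, margin:-margin]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def _objective(params12: np.ndarray, donor_f: np.ndarray,
               acceptor_f: np.ndarray, margin: int) -> float:
    model = AlignmentModel(params12, donor_f.shape)
    return -_pearson(_warp(donor_f, model), acceptor_f, margin)


def fit_alignment(donor_ref: np.ndarray, acceptor_ref: np.ndarray, *,
                  corr_floor: float = 0.5, bin_factor: int = 4,
                  preprocess: bool = True) -> AlignmentModel:
    """Fit the 12-parameter donor->acceptor map on a reference image pair.

    Staged optimization: (1) translation only on binned feature images,
    (2) all 12 parameters on the binned images, (3) all parameters on
    the full-size feature images; each stage warm-starts the next with
    a restarted Nelder-Mead simplex.

    Raises :class:`RegistrationError` if the achieved correlation falls
    below ``corr_floor``.
    """
    if donor_ref.shape != acceptor_ref.shape:
        raise ValueError("reference images must share a shape")
    shape = donor_ref.shape
    if preprocess:
        f_d = preprocess_for_alignment(donor_ref)
        f_a = preprocess_for_alignment(acceptor_ref)
    else:
        f_d = np.asarray(donor_ref, dtype=float)
        f_a = np.asarray(acceptor_ref, dtype=float)
    if f_d.max() == 0 or f_a.max() == 0:
        raise RegistrationError("reference images contain no structure")

    f_d_b = block_reduce(f_d, (bin_factor, bin_factor), np.mean)
    f_a_b = block_reduce(f_a, (bin_factor, bin_factor), np.mean)
    margin_b = max(2, min(f_d_b.shape) // 12)
    margin_f = max(4, min(shape) // 12)
    sy, sx = _half_spans(shape)

    # Stage 1: translation only, on binned images, from a coarse grid.
    def trans_obj(t):
        p = np.concatenate([_IDENTITY_X, _IDENTITY_Y])
        p[0], p[6] = t
        return _objective(p, f_d_b, f_a_b, margin_b)

    grid = np.arange(-12.0, 12.5, 2.0)
    best_t, best_v = (0.0, 0.0), trans_obj((0.0, 0.0))
    for gx in grid:
        for gy in grid:
            t = (gx / sx, gy / sy)
            v = trans_obj(t)
            if v < best_v:
                best_t, best_v = t, v
    res1 = minimize(trans_obj, best_t, method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
    p1 = np.concatenate([_IDENTITY_X, _IDENTITY_Y])
    p1[0], p1[6] = res1.x

    # Stage 2: all 12 parameters on binned images.
    p2 = _simplex_restarts(p1, f_d_b, f_a_b, margin_b, maxiter=2500)
    # Stage 3: all parameters on full-size feature images.
    p3 = _simplex_restarts(p2, f_d, f_a, margin_f, maxiter=2500)

    quality = -_objective(p3, f_d, f_a, margin_f)
    model = AlignmentModel(p3, shape, fit_quality=quality)
    if quality < corr_floor:
        raise RegistrationError(
            f"registration correlation {quality:.3f} below floor {corr_floor}")
    return model


def _simplex_restarts(p0: np.ndarray, f_d: np.ndarray, f_a: np.ndarray,
                      margin: int, maxiter: int, n_restarts: int = 1
                      ) -> np.ndarray:
    p = np.asarray(p0, dtype=float)
    prev = _objective(p, f_d, f_a, margin)
    for _ in range(1 + n_restarts):
        res = minimize(_objective, p, args=(f_d, f_a, margin),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8,
                                "maxiter": maxiter, "adaptive": True})
        p = res.x
        if prev - res.fun < 1e-8:
            break
        prev = res.fun
    return p


def apply_alignment(image: np.ndarray, model: AlignmentModel) -> np.ndarray:
    """Resample the donor image onto acceptor coordinates.

    Bilinear interpolation at the model's sampling positions; samples
    that fall outside the donor frame are returned as NaN (invalid),
    never extrapolated.  With an identity model, interior pixels are
    returned bit-exactly.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(model.reference_shape):
        raise ValueError("image shape does not match model reference_shape")
    if not model.is_invertible():
        raise ValueError("alignment model is not invertible over the field")
    rows, cols = np.indices(image.shape)
    src_r, src_c = model.map_coords(rows, cols)
    out = map_coordinates(image, [src_r, src_c], order=1,
                          mode="constant", cval=np.nan)
    oob = ((src_r < 0) | (src_r > image.shape[0] - 1)
           | (src_c < 0) | (src_c > image.shape[1] - 1))
    out[oob] = np.nan
    return out
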