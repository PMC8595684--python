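"""Camera and illumination corrections.

Four correction images/factors remove camera artifacts before ratio
computation:

* dark image (per camera): per-pixel median of unilluminated frames,
  applied by subtraction (clipped at zero);
* half-chip image (per camera): the two camera halves have slightly
  different sensitivity; the ratio of mean intensity in the two rows
  above versus below the chip midline gives a single factor applied
  multiplicatively to the bottom half;
* dust image (per camera): a dim spot from dust in the light path is
  flagged against a broad-Gaussian-smoothed dye image and restored,
  multiplicatively, to the smooth-field value;
* ratio-correction image: a systematic top-to-bottom gradient in the
  measured FRET ratio is estimated from a population of unstimulated
  cells (per-pixel median -> 24x24 block median -> Gaussian smooth ->
  upsample -> rescale to mean 1) and divided out of ratio images.

The dark, half-chip, and dust corrections apply to raw frames (in that
order); the ratio correction applies to ratio images downstream.
All Gaussian filters use reflective boundaries to avoid edge darkening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.transform import resize


@dataclass
class CorrectionSet:
    """Per-camera correction images plus the shared ratio correction.

    Cameras are keyed "donor" / "acceptor".  Multiplicative fields must
    be strictly positive; the ratio correction is normalized to mean 1
    over its valid pixels so absolute FRET levels are preserved.
    """

    dark: dict[str, np.ndarray] = field(default_factory=dict)
    half_chip: dict[str, np.ndarray] = field(default_factory=dict)
    dust: dict[str, np.ndarray] = field(default_factory=dict)
    ratio_correction: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, group in (("half_chip", self.half_chip),
                            ("dust", self.dust)):
            for cam, img in group.items():
                img = np.asarray(img)
                if not np.all(np.isfinite(img)) or np.any(img <= 0):
                    raise ValueError(
                        f"{name}[{cam}] must be strictly positive and finite")
        for cam, img in self.dark.items():
            if np.any(np.asarray(img) < 0):
                raise ValueError(f"dark[{cam}] must be non-negative")

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "CorrectionSet":
        ones = np.ones(shape)
        zeros = np.zeros(shape)
        return cls(dark={c: zeros.copy() for c in ("donor", "acceptor")},
                   half_chip={c: ones.copy() for c in ("donor", "acceptor")},
                   dust={c: ones.copy() for c in ("donor", "acceptor")},
                   ratio_correction=ones.copy())

    # -- persistence: multi-image TIFF + JSON manifest -----------------
    def save(self, tiff_path, manifest_path) -> None:
        pages = []
        names = []
        for group, tag in ((self.dark, "dark"), (self.half_chip, "half_chip"),
                           (self.dust, "dust")):
            for cam in sorted(group):
                pages.append(np.asarray(group[cam], dtype=np.float32))
                names.append(f"{tag}:{cam}")
        if self.ratio_correction is not None:
            pages.append(np.asarray(self.ratio_correction, dtype=np.float32))
            names.append("ratio_correction")
        tifffile.imwrite(tiff_path, np.stack(pages))
        with open(manifest_path, "w") as fh:
            json.dump({"pages": names, "provenance": self.provenance}, fh,
                      indent=1)

    @classmethod
    def load(cls, tiff_path, manifest_path) -> "CorrectionSet":
        pages = tifffile.imread(tiff_path)
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        out = cls(provenance=manifest.get("provenance", {}))
        for name, page in zip(manifest["pages"], np.atleast_3d(pages)):
            page = np.asarray(page, dtype=float)
            if name == "ratio_correction":
                out.ratio_correction = page
            else:
                tag, cam = name.split(":")
                getattr(out, tag)[cam] = page
        return out


def build_dark_correction(dark_frames: np.ndarray) -> np.ndarray:
    """Per-pixel median over a stack of >= 2 unilluminated frames."""
    dark_frames = np.asarray(dark_frames, dtype=float)
    if dark_frames.ndim != 3 or dark_frames.shape[0] < 2:
        raise ValueError("need a stack of at least 2 dark frames")
    return np.median(dark_frames, axis=0)


def build_half_chip_correction(dye_median: np.ndarray,
                               mid_row: int | None = None) -> np.ndarray:
    """Half-chip sensitivity step from a median uniform-dye image.

    factor = mean(two rows above the midline) / mean(two rows below);
    the returned field is 1 on the top half and ``factor`` on the
    bottom half, applied by multiplication.
    """
    dye = np.asarray(dye_median, dtype=float)
    if dye.ndim != 2 or dye.shape[0] < 4:
        raise ValueError("dye image needs at least 4 rows")
    mid = dye.shape[0] // 2 if mid_row is None else int(mid_row)
    above = dye[mid - 2:mid].mean()
    below = dye[mid:mid + 2].mean()
    if below == 0 or above == 0:
        raise ValueError("zero mean in half-chip reference rows: "
                         "invalid dye image")
    factor = above / below
    out = np.ones_like(dye)
    out[mid:] = factor
    return out


def build_dust_correction(dye_median: np.ndarray, *,
                          smooth_sigma: float = 30.0,
                          spot_sigma: float = 10.0,
                          dim_threshold: float = 0.98,
                          max_flagged_fraction: float = 0.10) -> np.ndarray:
    """Multiplicative field restoring a dust dim spot to the smooth field.

    The dye image is smoothed with a broad Gaussian (sigma 30); pixels
    whose dye/smooth ratio falls below ``dim_threshold`` are flagged.
    The flagged mask is feathered with a sigma-10 Gaussian and combined
    with the dye image so flagged pixels are restored to their
    smooth-field value; non-flagged pixels map to exactly 1.
    """
    dye = np.asarray(dye_median, dtype=float)
    if np.any(dye <= 0):
        raise ValueError("dye image must be strictly positive")
    smooth = gaussian_filter(dye, smooth_sigma, mode="reflect")
    flagged = (dye / smooth) < dim_threshold
    if flagged.mean() > max_flagged_fraction:
        raise ValueError("flagged dust area exceeds "
                         f"{max_flagged_fraction:.0%} of the chip: "
                         "bad calibration image")
    if not flagged.any():
        return np.ones_like(dye)
    # clean-field estimate inside the spot: sigma-10 normalized
    # convolution of the *unflagged* dye pixels, so the dim spot itself
    # does not bias the estimate
    good = (~flagged).astype(float)
    clean = (gaussian_filter(dye * good, spot_sigma, mode="reflect")
             / np.clip(gaussian_filter(good, spot_sigma, mode="reflect"),
                       1e-9, None))
    # feathered weight: 1 well inside the spot, tapering at its rim,
    # and exactly 0 outside the flagged mask
    weight = np.clip(3.0 * gaussian_filter(flagged.astype(float),
                                           spot_sigma, mode="reflect"),
                     0.0, 1.0)
    weight[~flagged] = 0.0
    restore = clean / dye
    out = np.ones_like(dye)
    out[flagged] = (1.0 - weight[flagged]) + weight[flagged] * restore[flagged]
    return out


def _block_median(img: np.ndarray, block: int) -> np.ndarray:
    """NaN-aware block-median downsample; border blocks are partial."""
    h, w = img.shape
    nbr = int(np.ceil(h / block))
    nbc = int(np.ceil(w / block))
    out = np.full((nbr, nbc), np.nan)
    for i in range(nbr):
        for j in range(nbc):
            tile = img[i * block:(i + 1) * block, j * block:(j + 1) * block]
            if np.any(np.isfinite(tile)):
                out[i, j] = np.nanmedian(tile)
    return out


def _fill_nan_nearest(img: np.ndarray) -> np.ndarray:
    """Fill NaN entries from nearest finite neighbors."""
    from scipy.ndimage import distance_transform_edt
    nan = ~np.isfinite(img)
    if not nan.any():
        return img
    if nan.all():
        raise ValueError("no finite values to interpolate from")
    idx = distance_transform_edt(nan, return_distances=False,
                                 return_indices=True)
    return img[tuple(idx)]


def build_ratio_correction(ratio_images: np.ndarray,
                           cell_masks: np.ndarray, *,
                           block: int = 24,
                           smooth_sigma: float = 5.0) -> np.ndarray:
    """Systematic ratio-gradient field from unstimulated calibration cells.

    Per-pixel median of in-mask ratios over the stack, 24x24 block-median
    downsample (empty blocks interpolated from neighbors), Gaussian
    smoothing (sigma 5), upsample to full size, and rescale to mean 1.
    Applied downstream by dividing ratio images.
    """
    ratio_images = np.asarray(ratio_images, dtype=float)
    cell_masks = np.asarray(cell_masks, dtype=bool)
    if ratio_images.shape != cell_masks.shape:
        raise ValueError("ratio stack and mask stack must share a shape")
    if ratio_images.ndim == 2:
        ratio_images = ratio_images[None]
        cell_masks = cell_masks[None]
    if not cell_masks.any():
        raise ValueError("no calibration cells: empty mask stack")
    stack = np.where(cell_masks, ratio_images, np.nan)
    import warnings
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_pixel = np.nanmedian(stack, axis=0)
    blocks = _block_median(per_pixel, block)
    blocks = _fill_nan_nearest(blocks)
    blocks = gaussian_filter(blocks, smooth_sigma, mode="reflect")
    full = resize(blocks, per_pixel.shape, order=1, mode="edge",
                  anti_aliasing=False)
    return full / full.mean()


def apply_corrections(frame: np.ndarray, camera: str,
                      corrections: CorrectionSet) -> np.ndarray:
    """Dark-subtract (clip at 0), then multiply half-chip and dust fields.

    The ratio correction is *not* applied here; it divides ratio images
    downstream.
    """
    frame = np.asarray(frame, dtype=float)
    out = frame
    if camera in corrections.dark:
        dark = corrections.dark[camera]
        if dark.shape != frame.shape:
            raise ValueError("dark image shape mismatch")
        out = np.clip(out - dark, 0.0, None)
    for group in (corrections.half_chip, corrections.dust):
        if camera in group:
            f = group[camera]
            if f.shape != frame.shape:
                raise ValueError("correction field shape mismatch")
            out = out * f
    return out
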