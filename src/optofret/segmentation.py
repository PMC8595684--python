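"""Cell segmentation on summed-channel images and frame-to-frame tracking.

The donor + acceptor sum image has better signal-to-noise than either
channel and is insensitive to FRET redistribution, so all masking runs
on it.  Segmentation: Gaussian smooth, unsharp masking (subtract a
broad sigma-25 blur), Otsu threshold, 8-connected components, and strict
minimum/maximum area filtering to drop fragments and aggregates.
Tracking links centroids between consecutive frames only when two
objects are mutually nearest neighbors within a distance gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize


@dataclass
class SegmentedObject:
    label: int
    centroid_px: tuple[float, float]  # (row, col)
    area_px: int
    bbox: tuple[int, int, int, int]


@dataclass
class LabelStack:
    """Per-frame integer label images with per-object measurements."""

    labels: np.ndarray  # (T, H, W) int
    objects: list[list[SegmentedObject]]
    pixel_size: float

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def centroids_um(self, t: int) -> np.ndarray:
        return np.array([o.centroid_px for o in self.objects[t]]) * self.pixel_size


@dataclass
class CellTrack:
    """Frame-indexed chain of segmented objects for one cell."""

    track_id: int
    frames: list[int]
    labels: list[int]  # object label in each frame's label image
    complete: bool = False
    qc: dict = field(default_factory=dict)

    def centroid_um(self, stack: LabelStack, t: int) -> np.ndarray:
        i = self.frames.index(t)
        for o in stack.objects[t]:
            if o.label == self.labels[i]:
                return np.asarray(o.centroid_px) * stack.pixel_size
        raise KeyError(f"track {self.track_id} has no object in frame {t}")

    def mask(self, stack: LabelStack, t: int) -> np.ndarray:
        i = self.frames.index(t)
        return stack.labels[t] == self.labels[i]


# ---------------------------------------------------------------------------
# Background estimation
# ---------------------------------------------------------------------------

def estimate_background(sum_stack: np.ndarray, *,
                        mode: str = "dense",
                        percentile: float = 1.5,
                        empty_well_profile: np.ndarray | None = None,
                        block: int = 24,
                        smooth_sigma: float = 1.0):
    """Estimate a background image and background-pixel mask.

    dense mode
        The dimmest pixels (default 1.5 percentile of the per-pixel
        minimum projection across all frames) define background; the
        empty-well profile image is scaled to match those pixels and
        returned as the background model to subtract.
    sparse mode (TIRF)
        Conservative background pixels (below the Otsu threshold of the
        mean image, lightly eroded by smoothing) feed a block-local
        median background image, smoothed and upsampled per the stack.

    Returns ``(background_image, background_mask)``.
    """
    stack = np.asarray(sum_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.size == 0:
        raise ValueError("empty stack")
    minproj = stack.min(axis=0)
    if mode == "dense":
        thresh = np.percentile(minproj, percentile)
        bg_mask = minproj <= thresh
        if not bg_mask.any():
            raise ValueError("no background pixels found: "
                             "dense-well mode misuse on a saturated field")
        # dim pixels select *where* background shows; the level comes
        # from the temporal median there (the min-projection itself is
        # biased low by noise)
        med = np.median(stack, axis=0)
        if empty_well_profile is None:
            level = np.median(med[bg_mask])
            return np.full(minproj.shape, level), bg_mask
        profile = np.asarray(empty_well_profile, dtype=float)
        scale = np.median(med[bg_mask] / profile[bg_mask])
        return scale * profile, bg_mask
    if mode == "sparse":
        mean_img = stack.mean(axis=0)
        smoothed = gaussian_filter(mean_img, 2.0, mode="reflect")
        try:
            otsu = threshold_otsu(smoothed)
        except ValueError:
            otsu = np.inf
        bg_mask = smoothed < otsu
        if not bg_mask.any():
            bg_mask = mean_img <= np.percentile(mean_img, percentile)
        masked = np.where(bg_mask, mean_img, np.nan)
        h, w = mean_img.shape
        nbr, nbc = int(np.ceil(h / block)), int(np.ceil(w / block))
        blocks = np.full((nbr, nbc), np.nan)
        for i in range(nbr):
            for j in range(nbc):
                tile = masked[i * block:(i + 1) * block,
                              j * block:(j + 1) * block]
                if np.any(np.isfinite(tile)):
                    blocks[i, j] = np.nanmedian(tile)
        from .corrections import _fill_nan_nearest
        blocks = _fill_nan_nearest(blocks)
        blocks = gaussian_filter(blocks, smooth_sigma, mode="reflect")
        bg = resize(blocks, mean_img.shape, order=1, mode="edge",
                    anti_aliasing=False)
        return bg, bg_mask
    raise ValueError(f"unknown background mode {mode!r}")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _otsu_separability(img: np.ndarray, thresh: float) -> float:
    """Between-class variance over total variance at the threshold.

    ~1 for a cleanly bimodal image; ~0.64 for a pure Gaussian (no
    structure).  Used to reject structureless frames where Otsu would
    otherwise threshold noise.
    """
    total = img.var()
    if total == 0:
        return 0.0
    fg = img > thresh
    p = fg.mean()
    if p in (0.0, 1.0):
        return 0.0
    between = p * (1 - p) * (img[fg].mean() - img[~fg].mean()) ** 2
    return float(between / total)


def segment_cells(sum_image: np.ndarray, *,
                  min_area_px: int = 80, max_area_px: int = 2000,
                  smooth_sigma: float = 2.0,
                  unsharp_sigma: float = 25.0,
                  min_separability: float = 0.75) -> np.ndarray:
    """Segment cells in a background-subtracted sum image.

    Gaussian smooth (sigma 2) -> unsharp mask (subtract a sigma-25
    blur) -> Otsu threshold -> 8-connected components -> discard
    components outside [min_area, max_area].  An empty label image is a
    valid result.  Masks are invariant to positive intensity rescaling.
    Frames whose Otsu separability falls below ``min_separability``
    (no real foreground/background structure) yield no objects.
    """
    img = np.asarray(sum_image, dtype=float)
    smoothed = gaussian_filter(img, smooth_sigma, mode="reflect")
    sharp = smoothed - gaussian_filter(smoothed, unsharp_sigma, mode="reflect")
    try:
        thresh = threshold_otsu(sharp)
    except ValueError:  # constant image
        return np.zeros(img.shape, dtype=np.int32)
    if _otsu_separability(sharp, thresh) < min_separability:
        return np.zeros(img.shape, dtype=np.int32)
    mask = sharp > thresh
    labels = cc_label(mask, connectivity=2)
    out = np.zeros_like(labels)
    nxt = 1
    for region in regionprops(labels):
        if min_area_px <= region.area <= max_area_px:
            out[labels == region.label] = nxt
            nxt += 1
    return out


def measure_labels(labels: np.ndarray) -> list[SegmentedObject]:
    return [SegmentedObject(label=r.label,
                            centroid_px=tuple(r.centroid),
                            area_px=int(r.area), bbox=tuple(r.bbox))
            for r in regionprops(labels)]


def build_label_stack(label_images: np.ndarray,
                      pixel_size: float) -> LabelStack:
    label_images = np.asarray(label_images)
    objects = [measure_labels(label_images[t])
               for t in range(label_images.shape[0])]
    return LabelStack(labels=label_images, objects=objects,
                      pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------

def _reciprocal_links(pts_a: np.ndarray, pts_b: np.ndarray,
                      max_link: float) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbor pairs within the gate.

    Exact distance ties break reciprocity conservatively: an object with
    two equidistant nearest candidates links to neither.
    """
    if len(pts_a) == 0 or len(pts_b) == 0:
        return []
    d = np.linalg.norm(pts_a[:, None, :] - pts_b[None, :, :], axis=2)
    links = []
    for i in range(len(pts_a)):
        row = d[i]
        j = int(np.argmin(row))
        if row[j] > max_link:
            continue
        if np.sum(row == row[j]) > 1:  # tie among i's nearest
            continue
        col = d[:, j]
        if np.sum(col == col.min()) > 1:  # tie among j's nearest
            continue
        if int(np.argmin(col)) == i:
            links.append((i, j))
    return links


def track_cells(stack: LabelStack, max_link_um: float = 10.0
                ) -> list[CellTrack]:
    """Link objects across frames by reciprocal nearest neighbors.

    Object i(t) links to j(t+1) iff each is the other's unique nearest
    neighbor and their centroid distance is <= ``max_link_um``.
    Unlinked objects start or end tracks; tracks spanning every frame
    are flagged ``complete``.
    """
    if stack.n_frames < 2:
        raise ValueError("tracking needs at least 2 frames")
    tracks: list[CellTrack] = []
    open_by_obj: dict[int, CellTrack] = {}  # object index -> track, frame t
    for t0 in range(stack.n_frames - 1):
        objs_a = stack.objects[t0]
        objs_b = stack.objects[t0 + 1]
        pts_a = np.array([o.centroid_px for o in objs_a]).reshape(-1, 2) \
            * stack.pixel_size
        pts_b = np.array([o.centroid_px for o in objs_b]).reshape(-1, 2) \
            * stack.pixel_size
        links = _reciprocal_links(pts_a, pts_b, max_link_um)
        linked_a = {i for i, _ in links}
        if t0 == 0:
            for i, o in enumerate(objs_a):
                tr = CellTrack(track_id=len(tracks), frames=[0],
                               labels=[o.label])
                tracks.append(tr)
                open_by_obj[i] = tr
        nxt_open: dict[int, CellTrack] = {}
        for i, j in links:
            tr = open_by_obj.get(i)
            if tr is None:
                tr = CellTrack(track_id=len(tracks), frames=[t0],
                               labels=[objs_a[i].label])
                tracks.append(tr)
            tr.frames.append(t0 + 1)
            tr.labels.append(objs_b[j].label)
            nxt_open[j] = tr
        for j, o in enumerate(objs_b):
            if j not in nxt_open:
                tr = CellTrack(track_id=len(tracks), frames=[t0 + 1],
                               labels=[o.label])
                tracks.append(tr)
                nxt_open[j] = tr
        open_by_obj = nxt_open
    for tr in tracks:
        tr.complete = len(tr.frames) == stack.n_frames
    return tracks
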