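"""Spatial signal-spread analysis.

Two complementary coordinate systems localize signaling within a cell:

* distance from the leading edge — the protruding edge region between
  consecutive frames defines the leading edge, and each in-cell pixel is
  assigned its *geodesic* (within-mask, 8-connected quasi-Euclidean)
  distance to it, so profiles respect cell shape and cannot cross
  background;
* distance from the stimulation site — pixels are sorted into concentric
  1-µm annuli around the focal stimulus pixel, and per-bin ratios are
  tracked as fold change over the frame immediately preceding the
  stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.graph import MCP_Geometric
from skimage.morphology import dilation, erosion

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ProtrusionMask:
    """Leading-edge region for one frame transition.

    ``provenance`` records the candidate component areas before the
    largest was kept and before neighbor-consistency trimming.
    """

    frame: int
    mask: np.ndarray
    provenance: dict


def detect_protrusion(mask_t: np.ndarray, mask_t1: np.ndarray,
                      prev_protrusion: np.ndarray | None = None,
                      next_protrusion: np.ndarray | None = None,
                      frame: int = 0) -> ProtrusionMask | None:
    """Protruding edge region between consecutive masks of one track.

    Candidate pixels are ``mask_t1 & ~mask_t``; the largest 8-connected
    component is kept.  When neighbor protrusions are given, pixels
    farther than one pixel (dilation-by-1) from either neighbor are
    trimmed and the largest remaining component is kept; an empty result
    (e.g. a one-frame transient) yields ``None``.
    """
    cand = np.asarray(mask_t1, bool) & ~np.asarray(mask_t, bool)
    if not cand.any():
        return None
    labels, n = ndimage.label(cand, structure=_EIGHT)
    areas = ndimage.sum_labels(cand, labels, index=np.arange(1, n + 1))
    keep = labels == (1 + int(np.argmax(areas)))
    prov = {"candidate_areas": sorted(areas.tolist(), reverse=True)}
    for neighbor in (prev_protrusion, next_protrusion):
        if neighbor is not None:
            keep &= dilation(np.asarray(neighbor, bool), _EIGHT)
    if not keep.any():
        return None
    labels, n = ndimage.label(keep, structure=_EIGHT)
    if n > 1:
        areas = ndimage.sum_labels(keep, labels, index=np.arange(1, n + 1))
        keep = labels == (1 + int(np.argmax(areas)))
    return ProtrusionMask(frame=frame, mask=keep, provenance=prov)


def detect_protrusions(masks: list[np.ndarray]) -> list[ProtrusionMask | None]:
    """Protrusion sequence for a track, with neighbor-consistency.

    ``masks[t]`` is the cell mask at frame t.  The protrusion at frame t
    is defined from the (t-1) -> t transition; the first frame has no
    transition and transitions lacking a previous or following candidate
    are rejected by the consistency requirement.
    """
    raw = [None]
    for t in range(1, len(masks)):
        raw.append(detect_protrusion(masks[t - 1], masks[t], frame=t))
    out: list[ProtrusionMask | None] = [None] * len(masks)
    for t in range(1, len(masks)):
        if raw[t] is None:
            continue
        prev = raw[t - 1].mask if (t - 1 >= 1 and raw[t - 1] is not None) else None
        nxt = raw[t + 1].mask if (t + 1 < len(masks) and raw[t + 1] is not None) else None
        if prev is None or nxt is None:
            continue  # no neighbor to validate against
        out[t] = detect_protrusion(masks[t - 1], masks[t], prev, nxt, frame=t)
    return out


def geodesic_distance(mask: np.ndarray, source: np.ndarray,
                      pixel_size: float = 1.0) -> np.ndarray:
    """Shortest within-mask path length from each mask pixel to the source.

    8-connected with step costs 1 and sqrt(2) (quasi-Euclidean),
    converted to micrometres.  Pixels outside the mask are NaN;
    in-mask pixels unreachable from the source are +inf.
    """
    mask = np.asarray(mask, bool)
    source = np.asarray(source, bool)
    if not source.any():
        raise ValueError("empty source")
    if not mask.any():
        raise ValueError("empty mask")
    if np.any(source & ~mask):
        raise ValueError("source must lie inside the mask")
    costs = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs)
    cum, _ = mcp.find_costs(np.argwhere(source))
    out = np.where(mask, cum * pixel_size, np.nan)
    return out


def edge_distance_profile(ratio_frames: list[np.ndarray],
                          masks: list[np.ndarray],
                          protrusions: list[ProtrusionMask | None],
                          pixel_size: float,
                          bin_width_um: float = 1.0,
                          max_distance_um: float | None = None
                          ) -> pd.DataFrame:
    """Mean ratio versus geodesic distance from the leading edge.

    Valid (finite) ratio pixels are pooled across all frames and cells
    by distance bin ``[k*w, (k+1)*w)`` and averaged; the profile is
    normalized to 1 at the leading edge (first bin).  Empty bins are
    reported as NaN.  Returns columns distance_um (bin centre), mean
    ratio (normalized), and n_px.
    """
    dists, vals = [], []
    for ratio, mask, prot in zip(ratio_frames, masks, protrusions):
        if prot is None or not prot.mask.any():
            continue
        d = geodesic_distance(mask, prot.mask, pixel_size)
        ok = np.isfinite(d) & np.isfinite(ratio)
        dists.append(d[ok])
        vals.append(ratio[ok])
    if not dists:
        raise ValueError("no frames with a defined protrusion")
    d = np.concatenate(dists)
    v = np.concatenate(vals)
    if max_distance_um is None:
        max_distance_um = d.max()
    n_bins = max(1, int(np.ceil(max_distance_um / bin_width_um)))
    idx = np.minimum((d / bin_width_um).astype(int), n_bins - 1)
    mean = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        sel = idx == k
        count[k] = sel.sum()
        if count[k]:
            mean[k] = v[sel].mean()
    if not np.isfinite(mean[0]) or mean[0] == 0:
        raise ValueError("no pixels at the leading edge to normalize by")
    return pd.DataFrame({
        "distance_um": (np.arange(n_bins) + 0.5) * bin_width_um,
        "ratio": mean / mean[0],
        "n_px": count,
    })


def screen_center_stim_cell(masks: list[np.ndarray],
                            centroids_um: np.ndarray,
                            frap_pixel: tuple[int, int],
                            stim_frame: int,
                            pixel_size: float, *,
                            min_edge_px: float = 4.0,
                            max_move_um: float = 4.0) -> tuple[bool, str]:
    """Keep/reject verdict for a center-stimulation cell.

    Rejects if the stimulation pixel falls outside the cell mask at the
    stimulation frame, if it lies less than ``min_edge_px`` pixels from
    the cell edge (Euclidean distance transform), or if any post-stimulus
    centroid displacement from the stimulation-frame centroid exceeds
    ``max_move_um``.  Deterministic and order-independent over cells.
    """
    r, c = int(round(frap_pixel[0])), int(round(frap_pixel[1]))
    mask = np.asarray(masks[stim_frame], bool)
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
        return False, "frap-outside-mask"
    edge_dist = ndimage.distance_transform_edt(mask)
    if edge_dist[r, c] < min_edge_px:
        return False, "edge-proximity"
    ref = np.asarray(centroids_um[stim_frame], dtype=float)
    for t in range(stim_frame + 1, len(masks)):
        if np.linalg.norm(np.asarray(centroids_um[t]) - ref) > max_move_um:
            return False, "motion"
    return True, "ok"


def register_stage_offsets(frames: list[np.ndarray],
                           offsets_um: np.ndarray,
                           pixel_size: float, *,
                           order: int = 1) -> list[np.ndarray]:
    """Shift each frame by its recorded stage offset so all frames share
    the first frame's coordinates.  ``offsets_um[t]`` is the stage
    (row, col) displacement of frame t relative to frame 0."""
    out = []
    for frame, off in zip(frames, np.asarray(offsets_um, dtype=float)):
        shift_px = -off / pixel_size
        arr = np.asarray(frame, dtype=float)
        out.append(ndimage.shift(arr, shift_px, order=order,
                                 mode="constant",
                                 cval=np.nan if order > 0 else 0.0))
    return out


def radial_profile(donor_frames: list[np.ndarray],
                   acceptor_frames: list[np.ndarray],
                   masks: list[np.ndarray],
                   frap_pixel: tuple[float, float],
                   pre_frame: int,
                   pixel_size: float,
                   times: np.ndarray | None = None, *,
                   ratio_correction: np.ndarray | None = None,
                   bin_width_um: float = 1.0,
                   min_pixels: int = 5) -> pd.DataFrame:
    """Concentric-annulus stimulus-response profile.

    Per frame, in-mask pixels are binned by the Euclidean distance of
    their centres to the stimulation pixel into 1-µm half-open annuli
    [k-1, k) µm (bin 1 nearest).  The ratio correction divides the
    acceptor before binning; per-bin ratio is mean acceptor / mean
    donor, and fold change divides by the same bin of the frame
    immediately preceding stimulation.  Bins with fewer than
    ``min_pixels`` valid pixels are reported missing (NaN); each bin
    also carries its annulus coverage fraction, since distal annuli may
    extend past the cell in some directions.

    Frames must already be registered to a common coordinate origin
    (see :func:`register_stage_offsets`) and bleach-corrected upstream
    if applicable.
    """
    shape = np.asarray(masks[0]).shape
    rr = np.arange(shape[0])[:, None] - frap_pixel[0]
    cc = np.arange(shape[1])[None, :] - frap_pixel[1]
    dist_um = pixel_size * np.hypot(rr, cc)
    max_bin = 0
    for m in masks:
        m = np.asarray(m, bool)
        if m.any():
            max_bin = max(max_bin, int(np.floor(dist_um[m].max())) + 1)
    bin_index = np.floor(dist_um / bin_width_um).astype(int) + 1  # 1-based
    annulus_area = np.bincount(bin_index.ravel(), minlength=max_bin + 2)

    rows = []
    per_frame_ratio = {}
    for t, (d, a, m) in enumerate(zip(donor_frames, acceptor_frames, masks)):
        d = np.asarray(d, dtype=float)
        a = np.asarray(a, dtype=float)
        if ratio_correction is not None:
            a = a / ratio_correction
        m = np.asarray(m, bool) & np.isfinite(d) & np.isfinite(a)
        ratios = {}
        for k in range(1, max_bin + 1):
            sel = m & (bin_index == k)
            n = int(sel.sum())
            if n >= min_pixels and d[sel].mean() > 0:
                ratios[k] = (a[sel].mean() / d[sel].mean(), n,
                             n / max(annulus_area[k], 1))
            else:
                ratios[k] = (np.nan, n, n / max(annulus_area[k], 1))
        per_frame_ratio[t] = ratios
    pre = per_frame_ratio[pre_frame]
    for t in range(len(donor_frames)):
        for k in range(1, max_bin + 1):
            ratio, n, cov = per_frame_ratio[t][k]
            pre_ratio = pre[k][0]
            fold = ratio / pre_ratio if np.isfinite(pre_ratio) else np.nan
            rows.append({
                "frame": t,
                "time_s": np.nan if times is None else float(times[t]),
                "bin_um": k,
                "n_px": n,
                "ratio": ratio,
                "fold_change": fold,
                "coverage": cov,
            })
    return pd.DataFrame(rows)


def select_edge_target(mask: np.ndarray, target_angle_deg: float,
                       centroid: tuple[float, float] | None = None
                       ) -> tuple[int, int]:
    """Perimeter pixel whose centroid-relative angle best matches the
    target angle.

    Angles are mathematical (counter-clockwise from +x) with the image
    y-axis pointing up in physical coordinates; ties are broken by the
    larger centroid distance.  Returns a (row, col) pixel.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.sum() == 1:
        raise ValueError("degenerate single-pixel mask")
    if centroid is None:
        rr, cc = np.nonzero(mask)
        centroid = (rr.mean(), cc.mean())
    perim = mask & ~erosion(mask, _EIGHT)
    rr, cc = np.nonzero(perim)
    dx = cc - centroid[1]
    dy = -(rr - centroid[0])  # image rows increase downward; flip to y-up
    ang = np.degrees(np.arctan2(dy, dx))
    diff = np.abs((ang - target_angle_deg + 180.0) % 360.0 - 180.0)
    dist = np.hypot(dx, dy)
    best = np.lexsort((-dist, diff))[0]
    return int(rr[best]), int(cc[best])
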