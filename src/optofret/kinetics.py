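"""Per-pixel FRET ratios with QC filters and stimulus-response kinetics.

Ratio images are acceptor/donor after background subtraction, mild
smoothing, and pixel QC (dim, near-saturating, or low-ratio pixels are
invalidated — dying cells show high donor autofluorescence and low
apparent FRET, so a conservative low-ratio cutoff of 0.8 removes them
per pixel).  Population time series use the ratio of channel means
(more robust than the mean of per-pixel ratios) normalized to the
pre-stimulus window; single-cell responses are summarized as the fold
change of a peak window over a control window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .corrections import CorrectionSet
from .datatypes import DualChannelStack

def _nanmean_quiet(x) -> float:
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    return float(x[ok].mean()) if ok.any() else float("nan")


# invalid-pixel reason codes
REASON_OUT_OF_MASK = 1
REASON_DIM = 2
REASON_SATURATED = 3
REASON_LOW_RATIO = 4


@dataclass
class RatioFrame:
    """Per-pixel acceptor/donor ratio with invalid pixels marked NaN.

    ``reasons`` carries a per-pixel code for why a pixel was
    invalidated (0 = valid).
    """

    ratio: np.ndarray
    reasons: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return self.reasons == 0


@dataclass
class FilterParams:
    """Pixel QC thresholds.

    Dim and near-saturation cutoffs default to 2% and 98% of the camera
    bit-depth range; the low-ratio (dead-cell) cutoff is 0.8.
    """

    saturation: float = 65535.0
    dim_fraction: float = 0.02
    saturate_fraction: float = 0.98
    low_ratio: float = 0.8

    @property
    def dim_level(self) -> float:
        return self.dim_fraction * self.saturation

    @property
    def saturate_level(self) -> float:
        return self.saturate_fraction * self.saturation


@dataclass
class ResponseWindows:
    """Analysis windows relative to the stimulus, each five frames at
    1.5 s spacing: two pre-stimulus controls and the peak window."""

    c1: tuple[float, float] = (-13.5, -7.5)
    c2: tuple[float, float] = (-6.0, 0.0)
    peak: tuple[float, float] = (4.5, 10.5)

    def __post_init__(self) -> None:
        order = [*self.c1, *self.c2, *self.peak]
        if not all(a <= b for a, b in zip(order[:-1], order[1:])):
            raise ValueError("windows must be ordered and non-overlapping")


@dataclass
class WellSeries:
    """Per-well mean-ratio time series, normalized over the pre-stimulus
    window; times are relative to the last frame before stimulation."""

    time: np.ndarray
    value: np.ndarray
    replicate_id: str = ""
    n_prestim: int = 0


def compute_ratio_image(donor: np.ndarray, acceptor: np.ndarray,
                        mask: np.ndarray,
                        corrections: CorrectionSet | None = None,
                        filters: FilterParams | None = None, *,
                        donor_background: float | np.ndarray = 0.0,
                        acceptor_background: float | np.ndarray = 0.0,
                        smooth_sigma: float = 1.0,
                        raw_donor: np.ndarray | None = None,
                        raw_acceptor: np.ndarray | None = None) -> RatioFrame:
    """Ratio image with QC: background-subtract, smooth (sigma 1),
    mask, divide, filter, and divide by the ratio-correction image.

    ``donor`` must already be aligned into acceptor coordinates.
    Saturation is checked on ``raw_donor``/``raw_acceptor`` when given
    (the pre-correction camera counts), else on the inputs.  A zero or
    negative donor at an in-mask pixel is invalidated as dim, never
    returned as infinity.
    """
    if filters is None:
        filters = FilterParams()
    donor = np.asarray(donor, dtype=float) - donor_background
    acceptor = np.asarray(acceptor, dtype=float) - acceptor_background
    if donor.shape != acceptor.shape or donor.shape != mask.shape:
        raise ValueError("donor, acceptor, and mask must share a shape")
    sat_d = raw_donor if raw_donor is not None else donor
    sat_a = raw_acceptor if raw_acceptor is not None else acceptor
    saturated = ((np.nan_to_num(sat_d) >= filters.saturate_level)
                 | (np.nan_to_num(sat_a) >= filters.saturate_level))
    if smooth_sigma > 0:
        donor = gaussian_filter(np.nan_to_num(donor), smooth_sigma,
                                mode="reflect")
        acceptor = gaussian_filter(np.nan_to_num(acceptor), smooth_sigma,
                                   mode="reflect")
    reasons = np.zeros(donor.shape, dtype=np.uint8)
    reasons[~mask] = REASON_OUT_OF_MASK
    dim = mask & ((donor <= filters.dim_level) | (acceptor <= filters.dim_level)
                  | (donor <= 0))
    reasons[dim] = REASON_DIM
    reasons[mask & saturated] = REASON_SATURATED
    ratio = np.full(donor.shape, np.nan)
    ok = reasons == 0
    ratio[ok] = acceptor[ok] / donor[ok]
    low = ok & (ratio < filters.low_ratio)
    reasons[low] = REASON_LOW_RATIO
    ratio[low] = np.nan
    if corrections is not None and corrections.ratio_correction is not None:
        ratio = ratio / corrections.ratio_correction
    return RatioFrame(ratio=ratio, reasons=reasons)


def _valid_channel_pixels(donor: np.ndarray, acceptor: np.ndarray,
                          filters: FilterParams) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        ok = ((donor > filters.dim_level) & (acceptor > filters.dim_level)
              & (donor < filters.saturate_level)
              & (acceptor < filters.saturate_level))
        ratio = np.where(donor > 0, acceptor / np.where(donor > 0, donor, 1.0),
                         0.0)
        ok &= ratio >= filters.low_ratio
    return ok


def population_timeseries(stack: DualChannelStack,
                          corrections: CorrectionSet | None = None,
                          filters: FilterParams | None = None, *,
                          stim_time: float | None = None,
                          donor_background: float | np.ndarray = 0.0,
                          acceptor_background: float | np.ndarray = 0.0,
                          replicate_id: str = "") -> WellSeries:
    """Whole-well mean-ratio time series, ratio-of-means per frame.

    Per frame, the mean valid donor and mean valid acceptor intensities
    are computed and *then* divided (ratio of means, not mean of
    ratios).  The series is normalized by its pre-stimulus mean and
    timestamps are shifted so the last pre-stimulus frame is at 0 s.
    Frames with no valid pixels carry NaN, never zero.
    """
    if filters is None:
        filters = FilterParams(saturation=float(
            stack.meta.get("saturation", 65535)))
    if stim_time is None:
        glb = [s.time for s in stack.stimuli if s.kind == "global"]
        stim_time = min(glb) if glb else None
    values = np.full(stack.n_frames, np.nan)
    for t in range(stack.n_frames):
        d = np.asarray(stack.donor[t], dtype=float) - donor_background
        a = np.asarray(stack.acceptor[t], dtype=float) - acceptor_background
        ok = _valid_channel_pixels(d, a, filters)
        if ok.any():
            md = d[ok].mean()
            if md > 0:
                values[t] = a[ok].mean() / md
    times = stack.times
    if stim_time is None:
        n_pre = stack.n_frames
        t0 = times[0]
    else:
        pre = np.flatnonzero(times < stim_time)
        if pre.size < 1:
            raise ValueError("need at least one pre-stimulus frame")
        n_pre = pre.size
        t0 = times[pre[-1]]
    pre_mean = _nanmean_quiet(values[:n_pre])
    return WellSeries(time=times - t0, value=values / pre_mean,
                      replicate_id=replicate_id, n_prestim=n_pre)


def single_cell_fold_change(cell_series: np.ndarray, times: np.ndarray,
                            windows: ResponseWindows | None = None, *,
                            baseline_frames: int = 10,
                            baseline_min: float = 0.95,
                            has_saturated_pixels: bool = False
                            ) -> tuple[float, float] | tuple[None, str]:
    """Peak/control and control/control fold changes for one cell.

    ``cell_series`` is the cell's mean-ratio trace, ``times`` in seconds
    relative to the stimulus (the last pre-stimulus frame at 0 s).  The
    mean is taken over the frames inside each closed window, then
    P/C2 and C1/C2 are returned.  Cells are excluded (returning
    ``(None, reason)``) if their pre-stimulus baseline over the first
    ``baseline_frames`` frames is below ``baseline_min`` (dead-cell
    rule), if either channel saturated, or if a window has no frames.
    """
    if windows is None:
        windows = ResponseWindows()
    cell_series = np.asarray(cell_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if has_saturated_pixels:
        return None, "saturated"
    baseline = _nanmean_quiet(cell_series[:baseline_frames])
    if not np.isfinite(baseline) or baseline < baseline_min:
        return None, "low-baseline"
    means = {}
    for name, (lo, hi) in (("c1", windows.c1), ("c2", windows.c2),
                           ("peak", windows.peak)):
        sel = (times >= lo) & (times <= hi)
        if not sel.any() or np.any(~np.isfinite(cell_series[sel])):
            return None, f"missing-frames:{name}"
        means[name] = cell_series[sel].mean()
    return means["peak"] / means["c2"], means["c1"] / means["c2"]


def response_histograms(fold_changes_by_experiment: dict[str, np.ndarray],
                        bin_edges: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean +/- SEM of per-experiment relative-frequency histograms.

    Each experiment's fold changes are histogrammed on shared edges and
    normalized to relative frequency; the mean and the standard error
    across experiments are returned per bin.  Empty groups are dropped.
    Returns ``(bin_edges, mean, sem)``.
    """
    if bin_edges is None:
        bin_edges = np.linspace(0.9, 1.4, 41)
    hists = []
    for name, values in fold_changes_by_experiment.items():
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            import warnings
            warnings.warn(f"experiment {name!r} has no cells; dropped")
            continue
        counts, _ = np.histogram(values, bins=bin_edges)
        hists.append(counts / counts.sum())
    if len(hists) < 1:
        raise ValueError("no non-empty experiment groups")
    hists = np.asarray(hists)
    mean = hists.mean(axis=0)
    if len(hists) >= 2:
        sem = hists.std(axis=0, ddof=1) / np.sqrt(len(hists))
    else:
        sem = np.full(mean.shape, np.nan)
    return bin_edges, mean, sem


def second_peak_ratio(series: WellSeries,
                      stim_times: tuple[float, float], *,
                      search_window_s: float = 15.0,
                      noise_floor: float = 0.005,
                      min_prominence: float = 0.2) -> float | None:
    """Relative amplitude of the second response peak to the first.

    Amplitudes are the maximum of (normalized series - 1) within
    ``search_window_s`` after each pulse (the first window is clipped
    at the second pulse).  Returns ``None`` when the second peak is not
    resolvable: the trace does not dip between the two responses by at
    least ``min_prominence`` of the smaller peak (e.g. very short
    inter-pulse delays).  A first amplitude at or below the noise floor
    signals a non-responding well.
    """
    t1, t2 = stim_times
    if t2 <= t1:
        raise ValueError("stimulus times must be increasing")
    t = series.time
    y = series.value - 1.0

    def window_amp(t0, t_hi):
        sel = (t >= t0) & (t <= t_hi)
        if not sel.any():
            return np.nan, None
        idx = np.flatnonzero(sel)
        k = idx[np.nanargmax(y[idx])]
        return y[k], k
    a1, k1 = window_amp(t1, min(t1 + search_window_s, t2))
    a2, k2 = window_amp(t2, t2 + search_window_s)
    if not np.isfinite(a1) or a1 <= noise_floor:
        raise ValueError("first-pulse amplitude at or below the noise "
                         "floor: non-responding well")
    if k2 is None or not np.isfinite(a2):
        return None
    between = (t > t[k1]) & (t < t[k2])
    if not between.any():
        return None
    dip = np.nanmin(y[between])
    prominence = min(a1, a2) - dip
    if prominence < max(noise_floor, min_prominence * min(a1, a2)):
        return None
    return float(a2 / a1)
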