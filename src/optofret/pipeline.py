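"""Configuration, validation, and end-to-end assay orchestration.

A run is described by one YAML/dict config with an ``assay`` kind
(``global``, ``center``, ``migration``, or ``profile``), a seed, an
output directory, and per-assay sections.  ``run_assay`` executes the
stages in acquisition order — corrections -> alignment -> segmentation/
tracking -> (bleach correction for the center assay) -> ratio ->
assay-specific analysis — writes flat CSV outputs plus a config echo,
and logs every QC rejection with its reason.  Runs are deterministic
for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ofio
from .bleach import BleachField, BleachModel, correct_ratio_series
from .datatypes import DualChannelStack, StimulusEvent
from .kinetics import (FilterParams, ResponseWindows, WellSeries,
                       _valid_channel_pixels, population_timeseries,
                       single_cell_fold_change)
from .migration import mean_squared_displacement, persistence_cosine
from .segmentation import (build_label_stack, estimate_background,
                           segment_cells, track_cells)
from .spatial import (detect_protrusions, edge_distance_profile,
                      radial_profile, screen_center_stim_cell)
from .synthetic import (KineticsParams, OpticsModel, SceneParams,
                        make_scene, render_frames)

log = logging.getLogger("optofret")


class ConfigError(ValueError):
    """Carries the full list of validation errors, never just the first."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid config:\n" + "\n".join(errors))


_THRESHOLD_DEFAULTS = {
    "min_area_px": 80,
    "max_area_px": 2000,
    "max_link_um": 10.0,
    "dim_fraction": 0.02,
    "saturate_fraction": 0.98,
    "low_ratio": 0.8,
    "baseline_min": 0.95,
    "baseline_frames": 10,
    "min_bin_pixels": 5,
    "max_move_um": 4.0,
    "min_edge_px": 4.0,
    "min_net_um": 5.0,
    "min_first_step_um": 5.0,
    "bg_percentile": 1.5,
}

_ASSAY_KINDS = ("global", "center", "migration", "profile")


def validate_config(config: dict) -> tuple[dict, list[str]]:
    """Fill defaults and range-check a run config.

    Returns ``(normalized_config, errors)`` with *all* errors reported
    at once; normalization is idempotent.
    """
    errors: list[str] = []
    cfg = deepcopy(config) if isinstance(config, dict) else {}
    if not isinstance(config, dict):
        errors.append("config must be a mapping")
    assay = cfg.get("assay")
    if assay is None:
        errors.append("missing required field 'assay'")
    elif assay not in _ASSAY_KINDS:
        errors.append(f"'assay' must be one of {_ASSAY_KINDS}, got {assay!r}")
    if "out_dir" not in cfg:
        errors.append("missing required field 'out_dir'")
    cfg.setdefault("seed", 0)
    if not isinstance(cfg["seed"], int):
        errors.append("'seed' must be an integer")
    cfg.setdefault("pixel_size", 0.65)
    if not (isinstance(cfg["pixel_size"], (int, float))
            and cfg["pixel_size"] > 0):
        errors.append("'pixel_size' must be > 0")
    cfg.setdefault("frame_interval", 1.5)
    if not (isinstance(cfg["frame_interval"], (int, float))
            and cfg["frame_interval"] > 0):
        errors.append("'frame_interval' must be > 0")
    th = cfg.setdefault("thresholds", {})
    for key, default in _THRESHOLD_DEFAULTS.items():
        th.setdefault(key, default)
    for key in th:
        if key not in _THRESHOLD_DEFAULTS:
            errors.append(f"unknown threshold {key!r}")
    if assay == "global":
        sec = cfg.setdefault("global", {})
        sec.setdefault("doses", [0.0, 1.0])
        sec.setdefault("wells_per_dose", 2)
        sec.setdefault("n_frames", 30)
        sec.setdefault("n_cells", 8)
        sec.setdefault("field_shape", [128, 128])
        sec.setdefault("stim_frame", 12)
        sec.setdefault("dead_fraction", 0.1)
        sec.setdefault("kinetics", None)
        sec.setdefault("speed_um_min", 10.0)
        sec.setdefault("cell_radius_um", 6.0)
        if sec["wells_per_dose"] < 1:
            errors.append("'global.wells_per_dose' must be >= 1")
        if sec["stim_frame"] < _THRESHOLD_DEFAULTS["baseline_frames"]:
            errors.append("'global.stim_frame' must leave pre-stimulus "
                          "baseline frames")
    elif assay == "center":
        sec = cfg.setdefault("center", {})
        if not sec.get("simulate", True):
            for need in ("stacks", "stim_log"):
                if need not in sec.get("paths", {}):
                    errors.append(
                        f"center assay requires 'center.paths.{need}'")
        sec.setdefault("simulate", True)
        sec.setdefault("n_frames", 12)
        sec.setdefault("stim_frame", 3)
        sec.setdefault("field_shape", [96, 96])
        sec.setdefault("pixel_size", 0.3)
        sec.setdefault("frame_interval", 1.0)
        sec.setdefault("power_uW", 4.3)
        sec.setdefault("spread_length_um", 3.0)
    elif assay == "migration":
        sec = cfg.setdefault("migration", {})
        if "tracks_csv" not in sec:
            sec.setdefault("simulate", True)
            sec.setdefault("n_cells", 30)
            sec.setdefault("n_experiments", 4)
            sec.setdefault("n_frames", 15)
            sec.setdefault("interval_s", 30.0)
    elif assay == "profile":
        sec = cfg.setdefault("profile", {})
        sec.setdefault("n_frames", 10)
        sec.setdefault("n_cells", 3)
        sec.setdefault("field_shape", [160, 160])
        sec.setdefault("pixel_size", 0.5)
        sec.setdefault("frame_interval", 10.0)
        sec.setdefault("speed_um_min", 20.0)
    return cfg, errors


# ---------------------------------------------------------------------------
# Shared analysis helpers
# ---------------------------------------------------------------------------

def extract_cell_traces(stack: DualChannelStack, thresholds: dict,
                        windows: ResponseWindows | None = None
                        ) -> tuple[WellSeries, pd.DataFrame, dict]:
    """Segment, track, and summarize single-cell responses in one well.

    Returns the well-level normalized series, a per-cell table
    (fold changes or the exclusion reason), and a QC summary whose
    counts reconcile (included + excluded = complete tracks detected).
    """
    filters = FilterParams(
        saturation=float(stack.meta.get("saturation", 65535)),
        dim_fraction=thresholds["dim_fraction"],
        saturate_fraction=thresholds["saturate_fraction"],
        low_ratio=thresholds["low_ratio"])
    donor = np.asarray(stack.donor, dtype=float)
    acceptor = np.asarray(stack.acceptor, dtype=float)
    sum_stack = donor + acceptor
    bg_sum, _ = estimate_background(
        sum_stack, mode="dense", percentile=thresholds["bg_percentile"])
    bg_d, _ = estimate_background(
        donor, mode="dense", percentile=thresholds["bg_percentile"])
    bg_a, _ = estimate_background(
        acceptor, mode="dense", percentile=thresholds["bg_percentile"])

    series = population_timeseries(stack, filters=filters,
                                   donor_background=bg_d,
                                   acceptor_background=bg_a)

    labels = np.stack([
        segment_cells(sum_stack[t] - bg_sum,
                      min_area_px=thresholds["min_area_px"],
                      max_area_px=thresholds["max_area_px"])
        for t in range(stack.n_frames)])
    lstack = build_label_stack(labels, stack.pixel_size)
    tracks = track_cells(lstack, max_link_um=thresholds["max_link_um"])
    complete = [t for t in tracks if t.complete]

    glb = [s.time for s in stack.stimuli if s.kind == "global"]
    stim_time = min(glb) if glb else None
    times = stack.times
    if stim_time is not None:
        pre = np.flatnonzero(times < stim_time)
        times_rel = times - times[pre[-1]]
    else:
        times_rel = times

    rows = []
    qc_counts: dict[str, int] = {}
    for tr in complete:
        trace = np.full(stack.n_frames, np.nan)
        saturated = False
        for frame, lab in zip(tr.frames, tr.labels):
            m = lstack.labels[frame] == lab
            d = donor[frame] - bg_d
            a = acceptor[frame] - bg_a
            if np.any(donor[frame][m] >= filters.saturate_level) or \
               np.any(acceptor[frame][m] >= filters.saturate_level):
                saturated = True
            ok = m & _valid_channel_pixels(d, a, filters)
            if ok.any() and d[ok].mean() > 0:
                trace[frame] = a[ok].mean() / d[ok].mean()
        result = single_cell_fold_change(
            trace, times_rel, windows,
            baseline_frames=thresholds["baseline_frames"],
            baseline_min=thresholds["baseline_min"],
            has_saturated_pixels=saturated)
        if result[0] is None:
            reason = result[1]
            qc_counts[reason] = qc_counts.get(reason, 0) + 1
            log.debug("track %d excluded: %s", tr.track_id, reason)
            rows.append({"track_id": tr.track_id, "p_over_c2": np.nan,
                         "c1_over_c2": np.nan, "included": False,
                         "reason": reason})
        else:
            rows.append({"track_id": tr.track_id, "p_over_c2": result[0],
                         "c1_over_c2": result[1], "included": True,
                         "reason": "ok"})
    per_cell = pd.DataFrame(
        rows, columns=["track_id", "p_over_c2", "c1_over_c2",
                       "included", "reason"])
    n_inc = int(per_cell["included"].sum()) if len(per_cell) else 0
    qc = {
        "tracks_detected": len(tracks),
        "tracks_complete": len(complete),
        "included": n_inc,
        "excluded": {k: int(v) for k, v in sorted(qc_counts.items())},
    }
    assert qc["included"] + sum(qc["excluded"].values()) == qc["tracks_complete"]
    return series, per_cell, qc


def simulate_global_well(seed: int, *, power: float, n_frames: int = 30,
                         n_cells: int = 8, field_shape=(128, 128),
                         stim_frame: int = 12, dead_fraction: float = 0.1,
                         pixel_size: float = 0.65,
                         frame_interval: float = 1.5,
                         kinetics: KineticsParams | None = None,
                         speed_um_min: float = 10.0,
                         cell_radius_um: float = 6.0,
                         noise: bool = True):
    """Render one global-stimulation well at the given stimulus power."""
    stim_time = stim_frame * frame_interval + 0.05
    # dose 0 is a sham stimulation: the event anchors the analysis
    # windows but drives nothing
    stimuli = [StimulusEvent(time=stim_time, kind="global", power=power)]
    params = SceneParams(
        field_shape=tuple(field_shape), pixel_size=pixel_size,
        frame_interval=frame_interval, n_frames=n_frames, n_cells=n_cells,
        dead_fraction=dead_fraction, stimuli=stimuli,
        speed_um_min=speed_um_min, cell_radius_um=cell_radius_um,
        kinetics=kinetics if kinetics is not None else KineticsParams())
    scene = make_scene(params, seed)
    optics = OpticsModel.identity(params.field_shape)
    return render_frames(scene, optics, noise=noise, seed=seed), scene


def diffusion_recovery_study(seed: int, n_replicates: int = 20, *,
                             true_diffusion: float = 0.5, b0: float = 0.3,
                             sigma0: float = 1.5, pixel_size: float = 0.3,
                             shape: tuple[int, int] = (64, 64),
                             sample_interval: float = 0.5,
                             t_end: float = 10.0) -> list[float]:
    """Recover the bleached-pool diffusion coefficient from simulation.

    Per replicate: render a focal-bleach recovery series (Gaussian dip,
    amplitude ``b0``, width ``sigma0`` µm, spreading at
    ``true_diffusion`` µm²/s, sampled every ``sample_interval`` s up to
    ``t_end`` s, with shot and camera noise), then fit (b0, sigma0, D)
    jointly by least squares.  Returns the fitted D per replicate.
    """
    from .synthetic import render_frap_calibration
    root = np.random.SeedSequence(seed)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    times = np.arange(0.0, t_end + 1e-9, sample_interval)
    optics = OpticsModel(shape=shape)
    fitted = []
    for child in root.spawn(n_replicates):
        sub = int(child.generate_state(1)[0] % (2 ** 31))
        truth = BleachModel(b0=b0, sigma0=sigma0, center=center,
                            pixel_size=pixel_size,
                            diffusion=true_diffusion)
        field = BleachField(truth, [(0.0, truth.calibration_power)])
        pre, post = render_frap_calibration(optics, field, times, seed=sub)
        pre_img = np.median(pre, axis=0) - optics.dark_offset
        frames = [p - optics.dark_offset for p in post]
        from .bleach import fit_recovery_series
        model = fit_recovery_series(frames, pre_img, center, times,
                                    pixel_size)
        fitted.append(model.diffusion)
    return fitted


# ---------------------------------------------------------------------------
# Assay runners
# ---------------------------------------------------------------------------

def run_assay(config: dict | str | Path) -> dict:
    """Validate the config, run the assay, and write the result bundle.

    Raises :class:`ConfigError` (listing every problem) on an invalid
    config.  Outputs are only written after the analysis completes, so
    partial bundles are never left behind silently.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg, errors = validate_config(config)
    if errors:
        raise ConfigError(errors)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    runner = {"global": _run_global, "center": _run_center,
              "migration": _run_migration, "profile": _run_profile}
    result = runner[cfg["assay"]](cfg, out)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return result


def _run_global(cfg: dict, out: Path) -> dict:
    sec = cfg["global"]
    th = cfg["thresholds"]
    root = np.random.SeedSequence(cfg["seed"])
    n_wells = len(sec["doses"]) * sec["wells_per_dose"]
    well_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in root.spawn(n_wells)]
    kin = (KineticsParams(**sec["kinetics"]) if sec["kinetics"] else None)
    dose_means = {}
    qc_all = {}
    planted_dead = {}
    per_cell_frames = []
    well_idx = 0
    for dose in sec["doses"]:
        series_list = []
        for w in range(sec["wells_per_dose"]):
            seed = well_seeds[well_idx]
            well_idx += 1
            stack, scene = simulate_global_well(
                seed, power=dose, n_frames=sec["n_frames"],
                n_cells=sec["n_cells"], field_shape=sec["field_shape"],
                stim_frame=sec["stim_frame"],
                dead_fraction=sec["dead_fraction"],
                pixel_size=cfg["pixel_size"],
                frame_interval=cfg["frame_interval"], kinetics=kin,
                speed_um_min=sec["speed_um_min"],
                cell_radius_um=sec["cell_radius_um"])
            series, per_cell, qc = extract_cell_traces(stack, th)
            per_cell["dose"] = dose
            per_cell["well"] = w
            per_cell_frames.append(per_cell)
            series_list.append(series)
            key = f"dose{dose}_well{w}"
            qc_all[key] = qc
            planted_dead[key] = int(sum(c.is_dead for c in scene.cells))
            log.info("%s: %d tracks, %d included", key,
                     qc["tracks_detected"], qc["included"])
        df = pd.DataFrame({"time_s": series_list[0].time})
        for w, s in enumerate(series_list):
            df[f"well{w}"] = s.value
        df["mean"] = df[[f"well{w}" for w in
                         range(sec["wells_per_dose"])]].mean(axis=1)
        df.to_csv(out / f"well_series_dose{dose}.csv", index=False)
        dose_means[dose] = df
    per_cell_all = pd.concat(per_cell_frames, ignore_index=True)
    per_cell_all.to_csv(out / "fold_changes.csv", index=False)
    with open(out / "qc_summary.json", "w") as fh:
        json.dump({"wells": qc_all, "planted_dead": planted_dead}, fh,
                  indent=1)
    return {"well_series": dose_means, "per_cell": per_cell_all,
            "qc": qc_all, "planted_dead": planted_dead}


def _run_center(cfg: dict, out: Path) -> dict:
    sec = cfg["center"]
    th = cfg["thresholds"]
    if not sec["simulate"]:
        raise NotImplementedError(
            "center assay on external stacks: provide simulated inputs")
    h, w = sec["field_shape"]
    pixel_size = sec["pixel_size"]
    stim_time = sec["stim_frame"] * sec["frame_interval"] + 0.05
    target = (h / 2.0, w / 2.0)
    params = SceneParams(
        field_shape=(h, w), pixel_size=pixel_size,
        frame_interval=sec["frame_interval"], n_frames=sec["n_frames"],
        n_cells=1, cell_radius_um=min(h, w) * pixel_size * 0.3,
        radius_sd_um=0.0, speed_um_min=0.5, dead_fraction=0.0,
        kinetics=KineticsParams(spread_length=sec["spread_length_um"],
                                k_off=0.05),
        stimuli=[StimulusEvent(time=stim_time, kind="focal", power=1.0,
                               target=target)])
    scene = make_scene(params, cfg["seed"])
    bleach_model = BleachModel(b0=0.3, sigma0=1.5, center=target,
                               pixel_size=pixel_size, diffusion=0.5,
                               alpha=1.0, calibration_power=37.0)
    bleach = BleachField(bleach_model, [(stim_time, sec["power_uW"])])
    stack = render_frames(scene, OpticsModel.identity((h, w)),
                          noise=True, seed=cfg["seed"], bleach=bleach)

    donor = np.asarray(stack.donor, dtype=float)
    acceptor = np.asarray(stack.acceptor, dtype=float)
    dark = stack.meta.get("dark_offset", 0.0)
    masks = [scene.label_stack[t] > 0 for t in range(scene.n_frames)]
    centroids = [c for c in scene.cells[0].centroids_um]
    keep, reason = screen_center_stim_cell(
        masks, np.asarray(centroids), target, sec["stim_frame"], pixel_size,
        min_edge_px=th["min_edge_px"], max_move_um=th["max_move_um"])
    log.info("center-stim screen: keep=%s reason=%s", keep, reason)
    ratios = []
    for t in range(scene.n_frames):
        d = donor[t] - dark
        a = acceptor[t] - dark
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(masks[t] & (d > 0), a / d, np.nan)
        ratios.append(r)
    corrected = correct_ratio_series(
        ratios, bleach_model, [(stim_time, sec["power_uW"])], stack.times)
    # bleach-correct the acceptor channel (equivalent to dividing the
    # ratio by 1 - alpha*b), then bin into concentric annuli
    acc_corr = []
    for t in range(scene.n_frames):
        b = bleach.fraction(stack.times[t], (h, w))
        acc_corr.append((acceptor[t] - dark)
                        / (1.0 - bleach_model.alpha * b))
    profile = radial_profile(
        [donor[t] - dark for t in range(scene.n_frames)],
        acc_corr, masks, target, sec["stim_frame"], pixel_size, stack.times,
        min_pixels=th["min_bin_pixels"])
    profile.to_csv(out / "radial_profile.csv", index=False)
    return {"screen": (keep, reason), "profile": profile,
            "corrected_ratios": corrected}


def _run_migration(cfg: dict, out: Path) -> dict:
    sec = cfg["migration"]
    th = cfg["thresholds"]
    if "tracks_csv" in sec:
        tracks = pd.read_csv(sec["tracks_csv"])
    else:
        tracks = simulate_migration_tracks(
            cfg["seed"], n_cells=sec["n_cells"],
            n_experiments=sec["n_experiments"], n_frames=sec["n_frames"],
            interval_s=sec["interval_s"])
    msd = mean_squared_displacement(tracks, min_net_um=th["min_net_um"])
    cosine = persistence_cosine(tracks,
                                min_first_step_um=th["min_first_step_um"])
    msd.to_csv(out / "msd.csv", index=False)
    cosine.to_csv(out / "persistence_cosine.csv", index=False)
    return {"msd": msd, "cosine": cosine, "tracks": tracks}


def simulate_migration_tracks(seed: int, *, n_cells: int = 30,
                              n_experiments: int = 4, n_frames: int = 15,
                              interval_s: float = 30.0,
                              speed_um_min: float = 12.0,
                              persistence_s: float = 240.0,
                              heading_sd: float = 0.7) -> pd.DataFrame:
    """Persistent-random-walk track table (tidy CSV layout)."""
    rng = np.random.default_rng(seed)
    rows = []
    rho = np.exp(-interval_s / persistence_s)
    for e in range(n_experiments):
        for c in range(n_cells):
            theta0 = rng.uniform(0, 2 * np.pi)
            theta = theta0
            speed = max(0.0, speed_um_min / 60.0 * rng.normal(1.0, 0.3))
            pos = rng.uniform(0, 500, 2)
            for f in range(n_frames):
                rows.append({"experiment": f"exp{e}", "cell": c, "frame": f,
                             "x_um": pos[0], "y_um": pos[1]})
                theta = (theta0 + (theta - theta0) * rho
                         + heading_sd * np.sqrt(1 - rho ** 2)
                         * rng.standard_normal())
                pos = pos + speed * interval_s * np.array(
                    [np.cos(theta), np.sin(theta)])
    return pd.DataFrame(rows)


def _run_profile(cfg: dict, out: Path) -> dict:
    sec = cfg["profile"]
    th = cfg["thresholds"]
    params = SceneParams(
        field_shape=tuple(sec["field_shape"]), pixel_size=sec["pixel_size"],
        frame_interval=sec["frame_interval"], n_frames=sec["n_frames"],
        n_cells=sec["n_cells"], speed_um_min=sec["speed_um_min"],
        heading_sd=0.15, persistence_s=600.0, dead_fraction=0.0,
        activity_mode="front")
    scene = make_scene(params, cfg["seed"])
    stack = render_frames(scene, OpticsModel.identity(params.field_shape),
                          noise=True, seed=cfg["seed"])
    donor = np.asarray(stack.donor, dtype=float)
    acceptor = np.asarray(stack.acceptor, dtype=float)
    dark = stack.meta.get("dark_offset", 0.0)
    frames, masks, prots = [], [], []
    for cell in scene.cells:
        cell_masks = [scene.mask(cell.index, t) for t in range(scene.n_frames)]
        cell_prots = detect_protrusions(cell_masks)
        for t in range(scene.n_frames):
            if cell_prots[t] is None:
                continue
            d = donor[t] - dark
            a = acceptor[t] - dark
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(cell_masks[t] & (d > 0), a / d, np.nan)
            frames.append(r)
            masks.append(cell_masks[t])
            prots.append(cell_prots[t])
    profile = edge_distance_profile(frames, masks, prots,
                                    params.pixel_size)
    profile.to_csv(out / "edge_profile.csv", index=False)
    return {"profile": profile, "scene": scene}
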