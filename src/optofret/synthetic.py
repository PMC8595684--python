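"""Ground-truth scene generation and dual-camera image rendering.

Generates scenes of membrane-sensor-expressing cells moving by a
persistent random walk, with a stimulus-driven activity field obeying a
phenomenological activation/adaptation ODE, and renders them into
realistic two-camera image stacks: inter-camera misalignment, vignetting,
a half-chip sensitivity step, a dust dim spot, dark offset, read noise,
Poisson shot noise, and (optionally) a diffusing photobleached sensor
pool.  Every downstream analysis stage is testable against the known
ground truth.

Activity model
--------------
Per cell (and, for focal stimuli, per pixel)::

    dA/dt  = k_in * (u0 + u(t)) * g(x) - (k_off + k1*F1 + k2*F2) * A
    dFi/dt = ai * A - di * Fi

with ``g(x) = exp(-d(x, target)^2 / (2 * spread_length^2))`` for focal
stimuli and ``g = 1`` for global stimuli.  The two feedback pools F1
(fast) and F2 (slow) produce the rapid attenuation, post-stimulus
undershoot, and slow recovery seen in stimulus-response traces; the
rates are phenomenological, not mechanistic.

Image model
-----------
The sensor redistributes emission between the donor and acceptor
channels without creating signal: expected donor photons are
``S * L_d / (1 + R)`` and acceptor photons ``S * L_a * R / (1 + R)``
with ``R = baseline_ratio * (1 + amp * A)`` and ``L`` the per-channel
illumination/sensitivity field.  The default FRET dynamic range ``amp``
is 0.11, on the scale of a red-shifted tandem-dimer sensor pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import map_coordinates

from .alignment import AlignmentModel
from .bleach import BleachField
from .datatypes import DualChannelStack, StimulusEvent


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class KineticsParams:
    """Rates of the phenomenological activation/adaptation ODE.

    Units: ``k_in`` per unit stimulus power per second, all other rates
    1/s, ``spread_length`` in µm.  Defaults are tuned so a brief
    saturating pulse gives a near-immediate peak, attenuation within
    tens of seconds, a shallow undershoot near half a minute, and
    recovery on the two-minute scale.
    """

    k_in: float = 12.5
    k_off: float = 0.04
    a1: float = 0.03
    d1: float = 0.05
    k1: float = 1.0
    a2: float = 0.01
    d2: float = 0.015
    k2: float = 0.8
    basal_drive: float = 0.0005  # constant input sustaining resting activity
    spread_length: float = 3.0  # µm, spatial footprint of focal stimuli

    def __post_init__(self) -> None:
        for name in ("k_in", "k_off", "a1", "d1", "k1", "a2", "d2", "k2",
                     "basal_drive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spread_length <= 0:
            raise ValueError("spread_length must be > 0")

    @property
    def feedback_load(self) -> float:
        """Steady-state feedback coefficient sum(ki*ai/di) (inf if di=0)."""
        load = 0.0
        for a, d, k in ((self.a1, self.d1, self.k1),
                        (self.a2, self.d2, self.k2)):
            if k * a > 0:
                if d == 0:
                    return np.inf
                load += k * a / d
        return load

    def steady_state(self) -> tuple[float, float, float]:
        """Resting (A, F1, F2) under the basal drive."""
        drive = self.k_in * self.basal_drive
        if drive == 0:
            return 0.0, 0.0, 0.0
        c = self.feedback_load
        if not np.isfinite(c):
            raise ValueError("no steady state: undecaying feedback pool "
                             "with basal drive")
        if c > 0:
            a = (-self.k_off + np.sqrt(self.k_off ** 2 + 4 * c * drive)) / (2 * c)
        elif self.k_off > 0:
            a = drive / self.k_off
        else:
            raise ValueError("no steady state: basal drive without decay")
        f1 = self.a1 * a / self.d1 if self.d1 > 0 else 0.0
        f2 = self.a2 * a / self.d2 if self.d2 > 0 else 0.0
        return a, f1, f2


@dataclass
class OpticsModel:
    """Camera/illumination model shared by both rendered channels.

    ``true_alignment`` is the sampling map applied to the donor channel
    (donor pixel p images the scene at ``true_alignment(p)``); the other
    fields are per-camera multiplicative sensitivity artifacts, the dark
    offset, read noise, and photon gain.
    """

    shape: tuple[int, int]
    true_alignment: AlignmentModel | None = None
    vignette_strength: float = 0.0  # fractional corner falloff, per camera
    half_chip_factor: float = 1.0  # bottom-half sensitivity on one camera
    half_chip_channel: str = "acceptor"
    dust_depth: float = 0.0  # fractional dimming at the dust spot centre
    dust_center: tuple[float, float] | None = None
    dust_sigma: float = 6.0  # px, Gaussian radius of the dust spot
    dust_channel: str = "donor"
    dark_offset: float = 100.0  # counts
    read_noise_sd: float = 3.0  # counts
    gain: float = 2.0  # counts per photon
    bit_depth: int = 16
    background_photons: float = 650.0  # empty-well photon level

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if not 0.0 <= self.dust_depth < 1.0:
            raise ValueError("dust depth must lie in [0, 1)")
        if self.vignette_strength < 0 or self.vignette_strength >= 1:
            raise ValueError("vignette must stay strictly positive")
        if self.half_chip_factor <= 0:
            raise ValueError("half-chip factor must be > 0")

    @classmethod
    def identity(cls, shape: tuple[int, int], *,
                 noiseless: bool = False) -> "OpticsModel":
        kw = {}
        if noiseless:
            kw = dict(dark_offset=0.0, read_noise_sd=0.0,
                      background_photons=0.0, gain=1.0)
        return cls(shape=tuple(shape), **kw)

    @classmethod
    def realistic(cls, shape: tuple[int, int], seed: int = 0) -> "OpticsModel":
        """Typical two-camera artifact set: a few-pixel misalignment with
        slight stretch and second-order warp, 12% vignetting, a 3%
        half-chip step, and a 20%-deep dust spot on the donor camera."""
        rng = np.random.default_rng(seed)
        model = AlignmentModel.identity(shape)
        sy, sx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        c = model.coefficients
        c[0] = rng.uniform(-4, 4) / sx
        c[6] = rng.uniform(-4, 4) / sy
        c[1] *= 1 + rng.uniform(-0.005, 0.005)
        c[8] *= 1 + rng.uniform(-0.005, 0.005)
        c[[3, 4, 5]] = rng.uniform(-2e-3, 2e-3, 3)
        c[[9, 10, 11]] = rng.uniform(-2e-3, 2e-3, 3)
        center = (shape[0] * rng.uniform(0.25, 0.75),
                  shape[1] * rng.uniform(0.25, 0.75))
        return cls(shape=tuple(shape), true_alignment=model,
                   vignette_strength=0.12, half_chip_factor=0.97,
                   dust_depth=0.2, dust_center=center, dust_sigma=6.0)

    # -- per-channel illumination/sensitivity fields -------------------
    def channel_field(self, channel: str) -> np.ndarray:
        h, w = self.shape
        rows = (np.arange(h)[:, None] - (h - 1) / 2) / ((h - 1) / 2)
        cols = (np.arange(w)[None, :] - (w - 1) / 2) / ((w - 1) / 2)
        r2 = (rows ** 2 + cols ** 2) / 2.0
        # slightly different vignette per camera so the flat-field suite
        # has channel-specific structure to remove
        strength = self.vignette_strength * (1.0 if channel == "donor" else 0.85)
        fieldv = 1.0 - strength * r2
        if channel == self.half_chip_channel and self.half_chip_factor != 1.0:
            fieldv = fieldv * np.where(np.arange(h)[:, None] >= h // 2,
                                       self.half_chip_factor, 1.0)
        if (channel == self.dust_channel and self.dust_depth > 0
                and self.dust_center is not None):
            rr = np.arange(h)[:, None] - self.dust_center[0]
            cc = np.arange(w)[None, :] - self.dust_center[1]
            spot = np.exp(-(rr ** 2 + cc ** 2) / (2 * self.dust_sigma ** 2))
            fieldv = fieldv * (1.0 - self.dust_depth * spot)
        return fieldv

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["true_alignment"] = (None if self.true_alignment is None
                               else self.true_alignment.to_dict())
        d["dust_center"] = (None if self.dust_center is None
                            else list(self.dust_center))
        return d


@dataclass
class SceneParams:
    """Configuration of a synthetic scene.

    Defaults emulate the global-stimulation assay geometry: 1.5 s frame
    interval, ~6 µm cell radius neutrophil-like cells moving at
    ~10 µm/min with a few-minute directional persistence, a 5% dead-cell
    fraction with a low constant ratio, and an 11% sensor dynamic range.
    """

    field_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.65  # µm/px
    frame_interval: float = 1.5  # s
    n_frames: int = 40
    n_cells: int = 10
    cell_radius_um: float = 6.0
    radius_sd_um: float = 0.8
    shape_irregularity: float = 0.08  # Fourier boundary-perturbation scale
    speed_um_min: float = 10.0
    persistence_s: float = 180.0  # OU relaxation time of the heading
    heading_sd: float = 0.5  # rad, stationary spread of the heading
    dead_fraction: float = 0.05
    baseline_ratio: float = 1.3
    baseline_ratio_sd: float = 0.04
    dead_ratio: float = 0.6  # constant low ratio of dead cells (< 0.8)
    response_amplitude: float = 0.11  # FRET dynamic range `amp`
    sensor_photons: float = 3000.0  # photons/px/frame inside a cell
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    stimuli: list[StimulusEvent] = field(default_factory=list)
    ode_dt_max: float = 0.05  # s, internal integration substep
    activity_mode: str = "ode"  # "ode" (stimulus-driven) or "front"
    # "front": a motion-polarized linear activity gradient, highest at the
    # leading edge, for edge-distance profile studies of migrating cells

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.dead_ratio >= 0.8:
            raise ValueError("dead cells must have baseline ratio < 0.8")
        t_end = self.n_frames * self.frame_interval
        for s in self.stimuli:
            if s.time > t_end:
                raise ValueError("stimulus after the end of the movie")
            if s.kind == "focal":
                r, c = s.target
                if not (0 <= r < self.field_shape[0]
                        and 0 <= c < self.field_shape[1]):
                    raise ValueError("focal target outside the field")


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class CellTruth:
    """Ground truth for one synthetic cell.

    ``centroids_um`` is (T, 2) as (row_um, col_um); ``activity`` is
    either (T,) (spatially uniform, global stimuli) or (T, h, w) on the
    bounding-box grid ``bbox`` (focal stimuli).  Dead cells carry zero
    activity and a constant low ``baseline_ratio``.
    """

    index: int
    centroids_um: np.ndarray
    radius_um: float
    boundary_amp: np.ndarray  # Fourier amplitudes of the boundary radius
    boundary_phase: np.ndarray
    baseline_ratio: float
    sensor_density: float
    is_dead: bool
    activity: np.ndarray
    bbox: tuple[int, int] | None = None  # (row0, col0) of a spatial activity map

    def activity_at(self, t_index: int, pixel: tuple[int, int] | None = None
                    ) -> float:
        if self.activity.ndim == 1:
            return float(self.activity[t_index])
        r0, c0 = self.bbox
        if pixel is None:
            raise ValueError("spatial activity map requires a pixel")
        return float(self.activity[t_index, pixel[0] - r0, pixel[1] - c0])


@dataclass
class GroundTruthScene:
    cells: list[CellTruth]
    field_shape: tuple[int, int]
    pixel_size: float
    frame_interval: float
    n_frames: int
    stimuli: list[StimulusEvent]
    seed: int
    label_stack: np.ndarray  # (T, H, W) int16; 0 = background, i+1 = cell i
    params: SceneParams | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def mask(self, cell_index: int, t_index: int) -> np.ndarray:
        return self.label_stack[t_index] == cell_index + 1

    def activity_map(self, t_index: int) -> np.ndarray:
        """Full-field activity image at one frame (0 outside cells)."""
        out = np.zeros(self.field_shape)
        for cell in self.cells:
            m = self.mask(cell.index, t_index)
            if cell.activity.ndim == 1:
                out[m] = cell.activity[t_index]
            else:
                r0, c0 = cell.bbox
                h, w = cell.activity.shape[1:]
                sub = np.zeros(self.field_shape)
                sub[r0:r0 + h, c0:c0 + w] = cell.activity[t_index]
                out[m] = sub[m]
        return out


# ---------------------------------------------------------------------------
# Activity ODE
# ---------------------------------------------------------------------------

def integrate_activity(frame_times: np.ndarray,
                       events: list[tuple[float, float, float, np.ndarray | float]],
                       kp: KineticsParams,
                       dt_max: float = 0.05,
                       state0: tuple | None = None) -> np.ndarray:
    """Integrate the activation/adaptation ODE, sampling at frame times.

    ``events`` is a list of ``(t_on, t_off, power, g)`` where ``g`` is
    the spatial gain (scalar or array).  Integration uses classical RK4
    on a grid refined to ``dt_max`` with breakpoints at every pulse edge
    and frame time, so the piecewise-constant drive is exact within each
    step.  Initial state defaults to the basal steady state.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    shapes = [np.shape(g) for *_unused, g in events if np.ndim(g) > 0]
    shape = shapes[0] if shapes else ()
    if state0 is None:
        a0, f10, f20 = kp.steady_state()
    else:
        a0, f10, f20 = state0
    A = np.full(shape, a0, dtype=float) if shape else float(a0)
    F1 = np.full(shape, f10, dtype=float) if shape else float(f10)
    F2 = np.full(shape, f20, dtype=float) if shape else float(f20)

    breaks = set(frame_times.tolist()) | {0.0}
    for t_on, t_off, _p, _g in events:
        breaks.add(t_on)
        breaks.add(t_off)
    t_end = float(frame_times.max()) if frame_times.size else 0.0
    breaks = sorted(b for b in breaks if 0.0 <= b <= t_end)

    def drive(t_mid):
        tot = kp.k_in * kp.basal_drive
        if shape:
            tot = np.full(shape, tot, dtype=float)
        for t_on, t_off, power, g in events:
            if t_on <= t_mid < t_off:
                tot = tot + kp.k_in * power * g
        return tot

    def rhs(A, F1, F2, u):
        dA = u - (kp.k_off + kp.k1 * F1 + kp.k2 * F2) * A
        dF1 = kp.a1 * A - kp.d1 * F1
        dF2 = kp.a2 * A - kp.d2 * F2
        return dA, dF1, dF2

    out = np.empty((frame_times.size,) + shape)
    frame_idx = {round(t, 9): i for i, t in enumerate(frame_times)}
    if round(0.0, 9) in frame_idx and breaks and breaks[0] == 0.0:
        out[frame_idx[0.0]] = A

    for b0, b1 in zip(breaks[:-1], breaks[1:]):
        span = b1 - b0
        if span <= 0:
            continue
        n = max(1, int(np.ceil(span / dt_max)))
        dt = span / n
        u = drive(b0 + 0.5 * dt)  # constant within (b0, b1)
        for _ in range(n):
            k1 = rhs(A, F1, F2, u)
            k2 = rhs(A + 0.5 * dt * k1[0], F1 + 0.5 * dt * k1[1],
                     F2 + 0.5 * dt * k1[2], u)
            k3 = rhs(A + 0.5 * dt * k2[0], F1 + 0.5 * dt * k2[1],
                     F2 + 0.5 * dt * k2[2], u)
            k4 = rhs(A + dt * k3[0], F1 + dt * k3[1], F2 + dt * k3[2], u)
            A = A + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            F1 = F1 + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            F2 = F2 + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        key = round(b1, 9)
        if key in frame_idx:
            out[frame_idx[key]] = A
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _cell_mask(shape, center_px, radius_px, amps, phases):
    """Rasterize a deformable disk: r(theta) = r0*(1 + sum ak cos(k theta + pk))."""
    r_max = radius_px * (1 + np.abs(amps).sum()) + 1.5
    r0 = max(0, int(np.floor(center_px[0] - r_max)))
    r1 = min(shape[0], int(np.ceil(center_px[0] + r_max)) + 1)
    c0 = max(0, int(np.floor(center_px[1] - r_max)))
    c1 = min(shape[1], int(np.ceil(center_px[1] + r_max)) + 1)
    rows = np.arange(r0, r1)[:, None] - center_px[0]
    cols = np.arange(c0, c1)[None, :] - center_px[1]
    dist = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    bound = radius_px * (1 + sum(a * np.cos((k + 2) * theta + p)
                                 for k, (a, p) in enumerate(zip(amps, phases))))
    sub = dist <= bound
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = sub
    return mask


def make_scene(params: SceneParams, seed: int) -> GroundTruthScene:
    """Generate a ground-truth scene; deterministic for a fixed seed.

    Cells are placed without overlap (bounded retries; failure signals an
    over-dense configuration), move by a persistent random walk with an
    Ornstein-Uhlenbeck heading, and carry an activity field integrated
    from the stimulus log.  All randomness flows from one seed through
    per-cell spawned substreams, so cell streams are order-independent.
    """
    root = np.random.SeedSequence(seed)
    place_rng = np.random.default_rng(root.spawn(1)[0])
    cell_seeds = root.spawn(params.n_cells + 1)[1:]

    h, w = params.field_shape
    t = np.arange(params.n_frames) * params.frame_interval
    radius_px_nom = params.cell_radius_um / params.pixel_size
    margin = radius_px_nom * (1 + 4 * params.shape_irregularity) + 2.0
    if 2 * margin >= min(h, w):
        raise ValueError("field too small for the requested cell radius")

    # non-overlapping initial placement with bounded retries
    centers = []
    radii = []
    max_tries = 500 * max(params.n_cells, 1)
    tries = 0
    while len(centers) < params.n_cells:
        if tries > max_tries:
            raise ValueError("could not place cells without overlap: "
                             "configuration too dense")
        tries += 1
        r_um = max(1.0, place_rng.normal(params.cell_radius_um,
                                         params.radius_sd_um))
        r_px = r_um / params.pixel_size
        pos = place_rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(pos - c)) > 1.2 * (r_px + rr) + 2
               for c, rr in zip(centers, radii)):
            centers.append(pos)
            radii.append(r_px)

    cells: list[CellTruth] = []
    label_stack = np.zeros((params.n_frames, h, w), dtype=np.int16)
    speed = params.speed_um_min / 60.0  # µm/s
    dt = params.frame_interval
    rho = np.exp(-dt / params.persistence_s)

    for i in range(params.n_cells):
        rng = np.random.default_rng(cell_seeds[i])
        is_dead = rng.random() < params.dead_fraction
        amps = rng.normal(0, params.shape_irregularity, 4)
        phases = rng.uniform(0, 2 * np.pi, 4)
        baseline = (params.dead_ratio if is_dead else
                    max(0.96, rng.normal(params.baseline_ratio,
                                         params.baseline_ratio_sd)))
        cell_speed = max(0.0, speed * rng.normal(1.0, 0.25))
        if is_dead:
            cell_speed = 0.0
        theta0 = rng.uniform(0, 2 * np.pi)
        theta = theta0
        pos_px = centers[i].copy()
        margin_i = radii[i] * (1 + np.abs(amps).sum()) + 1.5
        centroids_um = np.empty((params.n_frames, 2))
        for ti in range(params.n_frames):
            centroids_um[ti] = pos_px * params.pixel_size
            mask = _cell_mask((h, w), pos_px, radii[i], amps, phases)
            label_stack[ti][mask] = i + 1
            # OU heading about the initial direction, reflective walls
            theta = (theta0 + (theta - theta0) * rho
                     + params.heading_sd * np.sqrt(1 - rho ** 2)
                     * rng.standard_normal())
            step_px = cell_speed * dt / params.pixel_size
            nxt = pos_px + step_px * np.array([np.sin(theta), np.cos(theta)])
            for ax, lim in ((0, h), (1, w)):
                if nxt[ax] < margin_i:
                    nxt[ax] = 2 * margin_i - nxt[ax]
                    theta0 = -theta0 if ax == 0 else np.pi - theta0
                    theta = -theta if ax == 0 else np.pi - theta
                elif nxt[ax] > lim - 1 - margin_i:
                    nxt[ax] = 2 * (lim - 1 - margin_i) - nxt[ax]
                    theta0 = -theta0 if ax == 0 else np.pi - theta0
                    theta = -theta if ax == 0 else np.pi - theta
            pos_px = nxt

        # activity field
        if params.activity_mode == "front" and not is_dead:
            cell_mask_any = (label_stack == i + 1).any(axis=0)
            rows_any = np.flatnonzero(cell_mask_any.any(axis=1))
            cols_any = np.flatnonzero(cell_mask_any.any(axis=0))
            r0, r1 = rows_any[0], rows_any[-1] + 1
            c0, c1 = cols_any[0], cols_any[-1] + 1
            gr = np.arange(r0, r1)[:, None] * params.pixel_size
            gc = np.arange(c0, c1)[None, :] * params.pixel_size
            activity = np.zeros((params.n_frames, r1 - r0, c1 - c0))
            heading = np.zeros(2)
            for ti in range(params.n_frames):
                if ti + 1 < params.n_frames:
                    step = centroids_um[ti + 1] - centroids_um[ti]
                    if np.linalg.norm(step) > 0:
                        heading = step / np.linalg.norm(step)
                # signed distance (µm) along the heading from the centroid;
                # linear ramp: 0 at the rear edge, 1 at the leading edge
                proj = ((gr - centroids_um[ti, 0]) * heading[0]
                        + (gc - centroids_um[ti, 1]) * heading[1])
                r_um = radii[i] * params.pixel_size
                activity[ti] = np.clip(0.5 + proj / (2.0 * r_um), 0.0, 1.0)
            bbox = (int(r0), int(c0))
        elif is_dead or not params.stimuli:
            activity = np.zeros(params.n_frames)
            bbox = None
            if not is_dead and params.kinetics.basal_drive > 0:
                a_ss, _, _ = params.kinetics.steady_state()
                activity = np.full(params.n_frames, min(a_ss, 1.0))
        else:
            focal = [s for s in params.stimuli if s.kind == "focal"]
            if focal:
                cell_mask_any = (label_stack == i + 1).any(axis=0)
                rows_any = np.flatnonzero(cell_mask_any.any(axis=1))
                cols_any = np.flatnonzero(cell_mask_any.any(axis=0))
                r0, r1 = rows_any[0], rows_any[-1] + 1
                c0, c1 = cols_any[0], cols_any[-1] + 1
                gr = np.arange(r0, r1)[:, None]
                gc = np.arange(c0, c1)[None, :]
                events = []
                for s in params.stimuli:
                    if s.kind == "focal":
                        d_um = params.pixel_size * np.hypot(gr - s.target[0],
                                                            gc - s.target[1])
                        g = np.exp(-d_um ** 2
                                   / (2 * params.kinetics.spread_length ** 2))
                    else:
                        g = np.ones((r1 - r0, c1 - c0))
                    events.append((s.time, s.time + s.duration, s.power, g))
                activity = integrate_activity(t, events, params.kinetics,
                                              params.ode_dt_max)
                bbox = (int(r0), int(c0))
            else:
                events = [(s.time, s.time + s.duration, s.power, 1.0)
                          for s in params.stimuli]
                activity = integrate_activity(t, events, params.kinetics,
                                              params.ode_dt_max)
                bbox = None

        cells.append(CellTruth(
            index=i, centroids_um=centroids_um, radius_um=radii[i] * params.pixel_size,
            boundary_amp=amps, boundary_phase=phases, baseline_ratio=float(baseline),
            sensor_density=params.sensor_photons, is_dead=bool(is_dead),
            activity=np.asarray(activity), bbox=bbox))

    return GroundTruthScene(
        cells=cells, field_shape=(h, w), pixel_size=params.pixel_size,
        frame_interval=params.frame_interval, n_frames=params.n_frames,
        stimuli=list(params.stimuli), seed=seed, label_stack=label_stack,
        params=params)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _expected_photons(scene: GroundTruthScene, t_index: int,
                      amp: float,
                      bleach: BleachField | None) -> tuple[np.ndarray, np.ndarray]:
    """Scene-side expected photon images (donor, acceptor), before camera
    fields, warp, background, and noise."""
    h, w = scene.field_shape
    S = np.zeros((h, w))
    R = np.ones((h, w))
    labels = scene.label_stack[t_index]
    for cell in scene.cells:
        m = labels == cell.index + 1
        if not m.any():
            continue
        S[m] = cell.sensor_density
        if cell.activity.ndim == 1:
            a_img = cell.activity[t_index]
            R[m] = cell.baseline_ratio * (1 + amp * a_img)
        else:
            r0, c0 = cell.bbox
            hh, ww = cell.activity.shape[1:]
            full = np.zeros((h, w))
            full[r0:r0 + hh, c0:c0 + ww] = cell.activity[t_index]
            R[m] = cell.baseline_ratio * (1 + amp * full[m])
    f_d = np.ones((h, w))
    f_a = np.ones((h, w))
    if bleach is not None:
        b = bleach.fraction(t_index * scene.frame_interval, (h, w))
        if np.any(b < 0) or np.any(b > 1):
            raise ValueError("bleach fraction must lie in [0, 1]")
        f_d = 1.0 - b
        f_a = (1.0 - b) * (1.0 - bleach.alpha * b)
    donor = S * f_d / (1.0 + R)
    acceptor = S * f_a * R / (1.0 + R)
    return donor, acceptor


def render_frames(scene: GroundTruthScene,
                  optics: OpticsModel | None = None, *,
                  noise: bool = True, seed: int | None = None,
                  bleach: BleachField | None = None) -> DualChannelStack:
    """Render a scene into a two-camera stack under an optics model.

    The donor channel is resampled through ``optics.true_alignment``
    (bilinear); per-channel illumination/sensitivity fields multiply the
    summed cell + background photon image; Poisson noise acts on photon
    counts, then gain, dark offset, Gaussian read noise, and saturation
    clipping at the configured bit depth (never silent rescaling).
    With ``noise=False`` the expected count images are returned as float.
    """
    if optics is None:
        optics = OpticsModel.identity(scene.field_shape)
    if tuple(optics.shape) != tuple(scene.field_shape):
        raise ValueError("optics shape must match the scene field")
    if optics.true_alignment is not None and not optics.true_alignment.is_invertible():
        raise ValueError("optics alignment model is not invertible")
    amp = scene.params.response_amplitude if scene.params is not None else 0.11
    if seed is None:
        seed = scene.seed
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(0xF0,)))
    L_d = optics.channel_field("donor")
    L_a = optics.channel_field("acceptor")
    # smooth nonzero background emulating an empty-well profile
    bg = optics.background_photons

    donor_stack = np.empty((scene.n_frames,) + tuple(scene.field_shape))
    acc_stack = np.empty_like(donor_stack)
    if optics.true_alignment is not None:
        rows, cols = np.indices(scene.field_shape)
        src = optics.true_alignment.map_coords(rows, cols)
    else:
        src = None
    for ti in range(scene.n_frames):
        d_ph, a_ph = _expected_photons(scene, ti, amp, bleach)
        d_ph = d_ph + bg
        a_ph = a_ph + bg
        if src is not None:
            d_ph = map_coordinates(d_ph, [src[0], src[1]], order=1,
                                   mode="nearest")
        d_ph = d_ph * L_d
        a_ph = a_ph * L_a
        if noise:
            d_counts = (optics.gain * rng.poisson(d_ph)
                        + optics.dark_offset
                        + rng.normal(0, optics.read_noise_sd, d_ph.shape))
            a_counts = (optics.gain * rng.poisson(a_ph)
                        + optics.dark_offset
                        + rng.normal(0, optics.read_noise_sd, a_ph.shape))
        else:
            d_counts = optics.gain * d_ph + optics.dark_offset
            a_counts = optics.gain * a_ph + optics.dark_offset
        sat = 2 ** optics.bit_depth - 1
        donor_stack[ti] = np.clip(d_counts, 0, sat)
        acc_stack[ti] = np.clip(a_counts, 0, sat)
    if noise:
        donor_stack = np.round(donor_stack).astype(np.uint16)
        acc_stack = np.round(acc_stack).astype(np.uint16)
    return DualChannelStack(
        donor=donor_stack, acceptor=acc_stack,
        pixel_size=scene.pixel_size, frame_interval=scene.frame_interval,
        stimuli=list(scene.stimuli),
        meta={"seed": seed, "noise": noise, "bit_depth": optics.bit_depth,
              "saturation": 2 ** optics.bit_depth - 1,
              "dark_offset": optics.dark_offset})


def render_bleach(scene: GroundTruthScene, bleach: BleachField,
                  optics: OpticsModel | None = None, *,
                  noise: bool = True, seed: int | None = None
                  ) -> DualChannelStack:
    """Render a scene with a diffusing photobleached sensor pool.

    The bleached fraction b(x, t) scales both emissions by (1 - b) and
    additionally biases the acceptor by (1 - alpha*b), so the observed
    ratio is the true ratio times (1 - alpha*b).  With b = 0 this is
    identical to :func:`render_frames` under the same seed.
    """
    return render_frames(scene, optics, noise=noise, seed=seed, bleach=bleach)


# ---------------------------------------------------------------------------
# Calibration-stack renderers (dark frames, uniform dye, empty wells)
# ---------------------------------------------------------------------------

def render_dark_frames(optics: OpticsModel, n: int = 79,
                       seed: int = 0) -> np.ndarray:
    """Unilluminated frames: dark offset plus read noise only."""
    rng = np.random.default_rng(seed)
    shape = (n,) + tuple(optics.shape)
    return (optics.dark_offset
            + rng.normal(0, optics.read_noise_sd, shape))


def render_dye_frames(optics: OpticsModel, channel: str, n: int = 50,
                      photons: float = 2000.0, seed: int = 0) -> np.ndarray:
    """Uniform-dye frames through one camera's illumination field."""
    rng = np.random.default_rng(seed)
    L = optics.channel_field(channel)
    out = np.empty((n,) + tuple(optics.shape))
    for i in range(n):
        ph = rng.poisson(photons * L)
        out[i] = (optics.gain * ph + optics.dark_offset
                  + rng.normal(0, optics.read_noise_sd, L.shape))
    return out


def render_frap_calibration(optics: OpticsModel, bleach: BleachField,
                            times: np.ndarray, *, photons: float = 3000.0,
                            n_pre: int = 5, seed: int = 0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """High-power focal-bleach calibration acquisition on a uniform
    sensor field: pre-bleach frames, then a recovery series sampled at
    ``times`` seconds after the pulse, with shot noise and camera noise.

    Returns ``(pre_stack (n_pre, H, W), post_stack (len(times), H, W))``
    in camera counts for the donor channel.
    """
    rng = np.random.default_rng(seed)
    L = optics.channel_field("donor")
    shape = tuple(optics.shape)

    def acquire(expected):
        return (optics.gain * rng.poisson(expected)
                + optics.dark_offset
                + rng.normal(0, optics.read_noise_sd, shape))

    pre = np.stack([acquire(photons * L) for _ in range(n_pre)])
    post = np.stack([acquire(photons * L * (1.0 - bleach.fraction(t, shape)))
                     for t in np.asarray(times, dtype=float)])
    return pre, post


def render_empty_well(optics: OpticsModel, channel: str, n: int = 20,
                      seed: int = 0) -> np.ndarray:
    """Cell-free frames: background photons through the channel field."""
    rng = np.random.default_rng(seed)
    L = optics.channel_field(channel)
    out = np.empty((n,) + tuple(optics.shape))
    for i in range(n):
        ph = rng.poisson(optics.background_photons * L)
        out[i] = (optics.gain * ph + optics.dark_offset
                  + rng.normal(0, optics.read_noise_sd, L.shape))
    return out
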