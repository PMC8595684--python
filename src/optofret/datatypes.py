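"""Shared container types for two-camera FRET image stacks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StimulusEvent:
    """One optogenetic stimulation pulse.

    Parameters
    ----------
    time : float
        Pulse onset, seconds from the start of the movie.
    kind : {"global", "focal"}
        Whole-field illumination versus a focused laser spot.
    power : float
        Relative stimulation power (dimensionless; focal powers may also
        be interpreted in microwatts by downstream bleach models).
    duration : float
        Pulse length in seconds.
    target : (row, col) or None
        Target pixel of a focal pulse; required iff ``kind == "focal"``.
    """

    time: float
    kind: str = "global"
    power: float = 1.0
    duration: float = 0.04
    target: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("global", "focal"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "focal" and self.target is None:
            raise ValueError("focal stimulus requires a target pixel")
        if self.time < 0:
            raise ValueError("stimulus time must be >= 0")
        if self.duration < 0:
            raise ValueError("stimulus duration must be >= 0")

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "kind": self.kind,
            "power": self.power,
            "duration": self.duration,
            "target": None if self.target is None else list(self.target),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEvent":
        t = d.get("target")
        return cls(
            time=d["time"], kind=d["kind"], power=d["power"],
            duration=d["duration"], target=None if t is None else tuple(t),
        )


@dataclass
class DualChannelStack:
    """Time-ordered donor/acceptor frame pairs from the two cameras.

    ``donor`` and ``acceptor`` are ``(T, H, W)`` arrays of camera counts
    (uint16 when rendered with noise, float otherwise).
    """

    donor: np.ndarray
    acceptor: np.ndarray
    pixel_size: float  # µm per pixel
    frame_interval: float  # seconds between frames
    stimuli: list[StimulusEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor)
        self.acceptor = np.asarray(self.acceptor)
        if self.donor.ndim != 3 or self.donor.shape != self.acceptor.shape:
            raise ValueError("donor/acceptor must be matching (T, H, W) stacks")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval
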