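"""Movie geometry, stimulation protocol, and the raw-stack container.

All spatial quantities are in micrometres (one pixel edge = ``pixel_size_um``)
and all temporal quantities in seconds. The defaults mirror a typical
InGaAs-camera recording of nanosensor-coated cultures: 0.74 um pixels,
5 frames/s with 200 ms exposure, and a 20 Hz / 5 s square-wave field
stimulation delivered through parallel bath electrodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

#: Edge length of one camera pixel in the sample plane (um).
DEFAULT_PIXEL_SIZE_UM = 0.74
#: Acquisition rate of the NIR-II camera (frames per second).
DEFAULT_FRAME_RATE_HZ = 5.0
#: Camera exposure per frame (s).
DEFAULT_EXPOSURE_S = 0.2
#: Electrical stimulation pulse-train frequency (Hz).
DEFAULT_STIM_FREQUENCY_HZ = 20.0
#: Duration of one stimulation epoch (s).
DEFAULT_STIM_DURATION_S = 5.0


@dataclass(frozen=True)
class MovieGeometry:
    """Spatial and temporal geometry of a fluorescence movie."""

    height: int
    width: int
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    n_frames: int = 150
    exposure_s: float = DEFAULT_EXPOSURE_S

    def __post_init__(self) -> None:
        for name in ("height", "width", "pixel_size_um", "frame_rate_hz",
                     "n_frames", "exposure_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel (um^2)."""
        return self.pixel_size_um ** 2

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        """Start time of each frame (s)."""
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical stimulation schedule within one movie.

    ``n_repeats`` counts stimulation epochs inside a single recording; the
    default is a single epoch per movie (repeated stimulations of one field
    of view are separate recordings).  When ``n_repeats > 1`` the epochs
    start every ``repeat_interval_s`` seconds.
    """

    stim_start_s: float = 10.0
    stim_duration_s: float = DEFAULT_STIM_DURATION_S
    stim_frequency_hz: float = DEFAULT_STIM_FREQUENCY_HZ
    n_repeats: int = 1
    repeat_interval_s: float = 15.0

    def __post_init__(self) -> None:
        if self.stim_start_s < 0:
            raise ValueError("stim_start_s must be >= 0")
        if self.stim_duration_s <= 0 or self.stim_frequency_hz <= 0:
            raise ValueError("stimulus duration and frequency must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_repeats > 1 and self.repeat_interval_s < self.stim_duration_s:
            raise ValueError("repeat_interval_s shorter than the stimulus itself")

    def repeat_windows(self) -> list[tuple[float, float]]:
        """(start, end) of every stimulation epoch, in seconds."""
        return [
            (self.stim_start_s + k * self.repeat_interval_s,
             self.stim_start_s + k * self.repeat_interval_s + self.stim_duration_s)
            for k in range(self.n_repeats)
        ]

    @property
    def last_stim_end_s(self) -> float:
        return self.repeat_windows()[-1][1]

    def validate_against(self, geometry: MovieGeometry) -> None:
        if self.last_stim_end_s > geometry.duration_s + 1e-9:
            raise ValueError(
                f"stimulation window ends at {self.last_stim_end_s:g} s but the "
                f"movie lasts only {geometry.duration_s:g} s"
            )


@dataclass
class MovieStack:
    """Raw fluorescence movie: ``frames[t, row, col]`` plus metadata."""

    frames: np.ndarray
    geometry: MovieGeometry
    protocol: Optional[StimulusProtocol] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, row, col) array")
        nt, nr, nc = self.frames.shape
        if (nt, nr, nc) != (self.geometry.n_frames, self.geometry.height, self.geometry.width):
            raise ValueError(
                f"frame array shape {self.frames.shape} does not match geometry "
                f"({self.geometry.n_frames}, {self.geometry.height}, {self.geometry.width})"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frames.min() < 0:
            raise ValueError("frame intensities must be non-negative")
        if self.protocol is not None:
            self.protocol.validate_against(self.geometry)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_index(self, t_s: float, *, how: str = "ceil") -> int:
        """Index of the frame covering time ``t_s``; clipped into range."""
        f = t_s * self.geometry.frame_rate_hz
        idx = math.ceil(f) if how == "ceil" else math.floor(f)
        return int(min(max(idx, 0), self.n_frames - 1))
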