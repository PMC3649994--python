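"""Shared data containers for movies, detections, tracks and nucleus geometry.

Conventions used throughout the package:

* image axes are ``(t, z, y, x)`` or ``(t, y, x)``, 0-based, origin top-left;
* physical coordinates are micrometres, converted through ``pixel_size_um``;
* speeds are reported in nm/s, arcs in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a configuration or input violates a documented precondition."""


@dataclass
class Movie:
    """A calibrated intensity movie, with or without a z axis."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    z_spacing_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ConfigurationError(
                f"movie data must be (t, y, x) or (t, z, y, x); got shape {self.data.shape}"
            )
        if self.data.ndim == 4 and (self.z_spacing_um is None or self.z_spacing_um <= 0):
            raise ConfigurationError("z-stack movie requires a positive z_spacing_um")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ConfigurationError("calibration fields must be positive")
        if self.data.shape[0] < 1:
            raise ConfigurationError("movie must contain at least one frame")
        if np.any(self.data < 0):
            raise ConfigurationError("intensities must be non-negative")

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])


@dataclass
class AlignedMovie:
    """Projected movie after drift correction; shifts are relative to frame 0."""

    frames: np.ndarray  # (t, y, x)
    shifts: np.ndarray  # (t, 2) as (dy, dx) px; shifts[0] == (0, 0)
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.frames.ndim != 3:
            raise ConfigurationError("aligned movie must be (t, y, x)")
        if self.shifts.shape != (self.frames.shape[0], 2):
            raise ConfigurationError("one (dy, dx) shift per frame required")


@dataclass
class Detection:
    """One aggregate observation in one projected frame."""

    frame: int
    y_um: float
    x_um: float
    peak: float
    diameter_um: float
    at_border: bool = False
    nucleus_id: int | None = None

    @property
    def yx_um(self) -> np.ndarray:
        return np.array([self.y_um, self.x_um])


@dataclass
class TrackEvent:
    frame: int
    kind: str  # "fusion" or "split"
    partner: int  # track_id of the other participant


@dataclass
class Track:
    """Ordered detections of one aggregate; frame indices strictly increase."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)
    events: list[TrackEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions_um(self) -> np.ndarray:
        """(n, 2) array of (y, x) positions in micrometres."""
        return np.array([[d.y_um, d.x_um] for d in self.detections], dtype=float)

    @property
    def gaps(self) -> list[int]:
        """Frame indices skipped inside the track span."""
        f = self.frames
        out: list[int] = []
        for a, b in zip(f[:-1], f[1:]):
            out.extend(range(a + 1, b))
        return out

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame


@dataclass
class NucleusGeometry:
    """Projected nucleus circle used for arc-coverage statistics."""

    center_y_um: float
    center_x_um: float
    radius_um: float
    nucleus_id: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ConfigurationError("nucleus radius must be positive")

    @property
    def center_um(self) -> np.ndarray:
        return np.array([self.center_y_um, self.center_x_um])


@dataclass
class GroundTruthTrack:
    """True 3D trajectory of one simulated aggregate on the nuclear envelope.

    ``positions_um`` holds (y, x, z) columns in absolute movie coordinates; the
    first two columns are the ideal 2D projection.  ``states`` labels every
    frame-to-frame step origin as ``run`` or ``pause``.
    """

    track_id: int
    nucleus_id: int
    start_frame: int
    positions_um: np.ndarray  # (n, 3): y, x, z
    diameters_um: np.ndarray  # (n,)
    states: np.ndarray  # (n,) of {"run", "pause"}

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(len(self.positions_um))

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.positions_um) - 1

    @property
    def projected_um(self) -> np.ndarray:
        return self.positions_um[:, :2]


@dataclass
class GroundTruthEvent:
    frame: int
    kind: str  # "fusion" or "split"
    track_id: int  # track ending (fusion) or child starting (split)
    partner: int  # surviving track (fusion) or parent (split)


@dataclass
class GroundTruth:
    """Everything the simulator knows: tracks, nucleus geometry, event log."""

    tracks: list[GroundTruthTrack]
    geometries: dict[int, NucleusGeometry]
    events: list[GroundTruthEvent] = field(default_factory=list)

    def tracks_of(self, nucleus_id: int) -> list[GroundTruthTrack]:
        return [t for t in self.tracks if t.nucleus_id == nucleus_id]

    def points_by_frame(self, n_frames: int, nucleus_id: int | None = None):
        """Per-frame (k, 2) arrays of projected true positions, with diameters.

        Returns a list of ``(yx_um, diameters_um)`` pairs indexed by frame.
        """
        out = [([], []) for _ in range(n_frames)]
        for t in self.tracks:
            if nucleus_id is not None and t.nucleus_id != nucleus_id:
                continue
            for i, f in enumerate(t.frames):
                if 0 <= f < n_frames:
                    out[f][0].append(t.positions_um[i, :2])
                    out[f][1].append(t.diameters_um[i])
        return [
            (np.array(p) if p else np.empty((0, 2)), np.array(d))
            for p, d in out
        ]
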