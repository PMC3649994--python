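"""Movement statistics of linked aggregate tracks.

All quantities are computed on aligned, projected coordinates:

* **projected speeds** — per linked interval, Euclidean 2D displacement over
  elapsed time, in nm/s; threshold fractions use a strictly-above convention
  at 40 nm/s and an inclusive one at 160 nm/s;
* **arc coverage** — a track's total projected path length re-expressed as
  the angle it would subtend if traveled along the nucleus circumference
  (``path / (2 pi R) * 360`` degrees), so larger angles mean larger distance
  traveled;
* **track overlap** — fraction of visited pixels shared by two or more
  rasterized tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _raster_line

from .models import ConfigurationError, NucleusGeometry, Track

#: (threshold nm/s, inclusive?) pairs used for headline speed fractions:
#: strictly above 40 nm/s, and at-or-above 160 nm/s.
DEFAULT_SPEED_THRESHOLDS = ((40.0, False), (160.0, True))


def _positions_and_frames(track) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(track, Track):
        return track.positions_um, track.frames
    pos = np.asarray(track, dtype=float)
    return pos, np.arange(len(pos))


def step_speeds(
    track,
    frame_interval_s: float,
    include_gap_intervals: bool = False,
) -> np.ndarray:
    """Per-interval projected speeds of one track, nm/s.

    Gap-spanning intervals are excluded by default; when included, their
    displacement is divided by the elapsed (multi-frame) time.  A track with
    fewer than two detections yields an empty array.
    """
    if frame_interval_s <= 0:
        raise ConfigurationError("frame_interval_s must be positive")
    pos, frames = _positions_and_frames(track)
    if len(pos) < 2:
        return np.empty(0)
    disp_nm = np.linalg.norm(np.diff(pos, axis=0), axis=1) * 1e3
    gaps = np.diff(frames)
    speeds = disp_nm / (gaps * frame_interval_s)
    if not include_gap_intervals:
        speeds = speeds[gaps == 1]
    return speeds


@dataclass
class SpeedDistribution:
    speeds: np.ndarray  # pooled interval speeds, nm/s
    bin_edges: np.ndarray
    histogram: np.ndarray  # fractions, sums to 1
    fractions_above: dict[float, float]
    inclusive: dict[float, bool]

    @property
    def n(self) -> int:
        return len(self.speeds)


def fraction_above(speeds: np.ndarray, threshold_nm_s: float, inclusive: bool = False) -> float:
    speeds = np.asarray(speeds)
    if speeds.size == 0:
        raise ConfigurationError("no speed intervals to summarize")
    hits = speeds >= threshold_nm_s if inclusive else speeds > threshold_nm_s
    return float(np.mean(hits))


def speed_distribution(
    tracks,
    frame_interval_s: float,
    thresholds=DEFAULT_SPEED_THRESHOLDS,
    bin_edges: np.ndarray | None = None,
    include_gap_intervals: bool = False,
    per_track_mean: bool = False,
) -> SpeedDistribution:
    """Pool interval speeds across tracks and summarize threshold fractions.

    ``per_track_mean=True`` summarizes each track by its mean interval speed
    instead of pooling raw intervals.
    """
    pooled: list[np.ndarray] = []
    for t in tracks:
        s = step_speeds(t, frame_interval_s, include_gap_intervals)
        if s.size == 0:
            continue
        pooled.append(np.array([s.mean()]) if per_track_mean else s)
    if not pooled:
        raise ConfigurationError("no speed intervals to summarize")
    speeds = np.concatenate(pooled)
    if bin_edges is None:
        top = max(250.0, float(speeds.max()) + 10.0)
        bin_edges = np.concatenate([np.arange(0.0, 250.0, 10.0), [top]])
    hist, edges = np.histogram(speeds, bins=bin_edges)
    hist = hist / hist.sum() if hist.sum() else hist.astype(float)
    fractions = {
        float(th): fraction_above(speeds, th, inc) for th, inc in thresholds
    }
    return SpeedDistribution(
        speeds=speeds,
        bin_edges=edges,
        histogram=hist,
        fractions_above=fractions,
        inclusive={float(th): bool(inc) for th, inc in thresholds},
    )


def arc_coverage(track, geometry: NucleusGeometry) -> float:
    """Track path length as an angle on the nucleus circumference, degrees."""
    if geometry.radius_um <= 0:
        raise ConfigurationError("nucleus radius must be positive")
    pos, _ = _positions_and_frames(track)
    if len(pos) < 2:
        return 0.0
    path_um = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    return path_um / (2.0 * np.pi * geometry.radius_um) * 360.0


@dataclass
class KinematicsSummary:
    """Per-nucleus movement summary: arc statistics plus speed fractions."""

    n_tracks: int
    arcs_deg: np.ndarray
    arc_mean_deg: float
    arc_max_deg: float
    arc_min_deg: float
    fractions_above: dict[float, float]
    n_intervals: int
    empty: bool = False
    nucleus_id: int | None = None

    def as_dict(self) -> dict:
        return {
            "nucleus_id": self.nucleus_id,
            "n_tracks": self.n_tracks,
            "arc_mean_deg": self.arc_mean_deg,
            "arc_max_deg": self.arc_max_deg,
            "arc_min_deg": self.arc_min_deg,
            "fractions_above": {str(k): v for k, v in self.fractions_above.items()},
            "n_intervals": self.n_intervals,
            "empty": self.empty,
        }


def summarize_nucleus(
    tracks,
    geometry: NucleusGeometry,
    frame_interval_s: float,
    min_track_length: int = 10,
    thresholds=DEFAULT_SPEED_THRESHOLDS,
) -> KinematicsSummary:
    """Arc and speed summary over tracks passing the minimum-length filter."""
    kept = [t for t in tracks if len(_positions_and_frames(t)[0]) >= min_track_length]
    if not kept:
        warnings.warn("no qualifying tracks; returning empty summary")
        return KinematicsSummary(
            n_tracks=0, arcs_deg=np.empty(0), arc_mean_deg=float("nan"),
            arc_max_deg=float("nan"), arc_min_deg=float("nan"),
            fractions_above={float(t): float("nan") for t, _ in thresholds},
            n_intervals=0, empty=True, nucleus_id=geometry.nucleus_id,
        )
    arcs = np.array([arc_coverage(t, geometry) for t in kept])
    dist = speed_distribution(kept, frame_interval_s, thresholds=thresholds)
    return KinematicsSummary(
        n_tracks=len(kept),
        arcs_deg=arcs,
        arc_mean_deg=float(arcs.mean()),
        arc_max_deg=float(arcs.max()),
        arc_min_deg=float(arcs.min()),
        fractions_above=dist.fractions_above,
        n_intervals=dist.n,
        nucleus_id=geometry.nucleus_id,
    )


def track_overlap_map(
    tracks,
    pixel_size_um: float,
    shape: tuple[int, int] | None = None,
) -> tuple[float, np.ndarray]:
    """Overlap fraction of rasterized track polylines.

    Each track visits the pixels of the 1-px-wide polyline through its
    detections; the overlap fraction is ``|pixels visited by >= 2 tracks| /
    |pixels visited by >= 1 track|``.  Returns the fraction and the count map.
    """
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be positive")
    track_pixels: list[set[tuple[int, int]]] = []
    max_y = max_x = 0
    for t in tracks:
        pos, _ = _positions_and_frames(t)
        px = np.round(pos / pixel_size_um).astype(int)
        visited: set[tuple[int, int]] = set()
        for (y0, x0), (y1, x1) in zip(px[:-1], px[1:]):
            ys, xs = _raster_line(y0, x0, y1, x1)
            visited.update(zip(ys.tolist(), xs.tolist()))
        if len(px) == 1:
            visited.add((int(px[0][0]), int(px[0][1])))
        if visited:
            my = max(y for y, _ in visited)
            mx = max(x for _, x in visited)
            max_y, max_x = max(max_y, my), max(max_x, mx)
        track_pixels.append(visited)
    if shape is None:
        shape = (max_y + 1, max_x + 1)
    counts = np.zeros(shape, dtype=int)
    for visited in track_pixels:
        for y, x in visited:
            if 0 <= y < shape[0] and 0 <= x < shape[1]:
                counts[y, x] += 1
    if len(track_pixels) < 2:
        warnings.warn("fewer than 2 tracks; overlap undefined, reporting 0")
        return 0.0, counts
    visited_any = int(np.count_nonzero(counts >= 1))
    if visited_any == 0:
        return 0.0, counts
    return float(np.count_nonzero(counts >= 2) / visited_any), counts
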