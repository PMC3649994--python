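"""Reading and writing the package's on-disk formats.

Movies travel as multi-page TIFF (TZYX or TYX) with a JSON sidecar carrying
the physical calibration (``pixel_size_um``, ``z_spacing_um``,
``frame_interval_s``); tables (ground truth, detections, tracks) are plain
CSV with documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .models import (
    ConfigurationError,
    Detection,
    GroundTruth,
    GroundTruthEvent,
    GroundTruthTrack,
    Movie,
    NucleusGeometry,
    Track,
    TrackEvent,
)


def sidecar_path(movie_path) -> Path:
    return Path(movie_path).with_suffix(".json")


def write_movie(path, movie: Movie) -> Path:
    """Write a movie as TIFF plus JSON calibration sidecar; returns the sidecar path."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(movie.data, dtype=np.float32), photometric="minisblack"
    )
    calib = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
        "z_spacing_um": movie.z_spacing_um,
        "axes": "TZYX" if movie.has_z else "TYX",
    }
    sp = sidecar_path(path)
    sp.write_text(json.dumps(calib, indent=1, sort_keys=True))
    return sp


def read_movie(path, calibration_path=None) -> Movie:
    path = Path(path)
    data = tifffile.imread(path)
    cp = Path(calibration_path) if calibration_path else sidecar_path(path)
    if not cp.exists():
        raise ConfigurationError(f"calibration sidecar not found: {cp}")
    calib = json.loads(cp.read_text())
    return Movie(
        data=data,
        pixel_size_um=float(calib["pixel_size_um"]),
        frame_interval_s=float(calib["frame_interval_s"]),
        z_spacing_um=calib.get("z_spacing_um"),
    )


# ---------------------------------------------------------------------------
# ground truth


def ground_truth_to_frames(gt: GroundTruth) -> pd.DataFrame:
    rows = []
    for t in gt.tracks:
        for i, f in enumerate(t.frames):
            y, x, z = t.positions_um[i]
            rows.append(
                {
                    "track_id": t.track_id,
                    "nucleus_id": t.nucleus_id,
                    "frame": int(f),
                    "y_um": y,
                    "x_um": x,
                    "z_um": z,
                    "diameter_um": t.diameters_um[i],
                    "state": t.states[i],
                }
            )
    return pd.DataFrame(rows)


def write_ground_truth(out_dir, gt: GroundTruth, stem: str = "ground_truth") -> dict[str, Path]:
    """Write tracks, events and nucleus geometries as three CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["tracks"] = out_dir / f"{stem}_tracks.csv"
    ground_truth_to_frames(gt).to_csv(paths["tracks"], index=False)
    paths["events"] = out_dir / f"{stem}_events.csv"
    pd.DataFrame(
        [
            {"frame": e.frame, "kind": e.kind, "track_id": e.track_id, "partner": e.partner}
            for e in gt.events
        ],
        columns=["frame", "kind", "track_id", "partner"],
    ).to_csv(paths["events"], index=False)
    paths["nuclei"] = out_dir / f"{stem}_nuclei.csv"
    pd.DataFrame(
        [
            {
                "nucleus_id": g.nucleus_id,
                "center_y_um": g.center_y_um,
                "center_x_um": g.center_x_um,
                "radius_um": g.radius_um,
            }
            for g in gt.geometries.values()
        ]
    ).to_csv(paths["nuclei"], index=False)
    return paths


def read_ground_truth(out_dir, stem: str = "ground_truth") -> GroundTruth:
    out_dir = Path(out_dir)
    frames = pd.read_csv(out_dir / f"{stem}_tracks.csv")
    events_df = pd.read_csv(out_dir / f"{stem}_events.csv")
    nuclei = pd.read_csv(out_dir / f"{stem}_nuclei.csv")
    tracks = []
    for tid, sub in frames.groupby("track_id"):
        sub = sub.sort_values("frame")
        tracks.append(
            GroundTruthTrack(
                track_id=int(tid),
                nucleus_id=int(sub["nucleus_id"].iloc[0]),
                start_frame=int(sub["frame"].iloc[0]),
                positions_um=sub[["y_um", "x_um", "z_um"]].to_numpy(),
                diameters_um=sub["diameter_um"].to_numpy(),
                states=sub["state"].to_numpy(dtype=str),
            )
        )
    events = [
        GroundTruthEvent(int(r.frame), str(r.kind), int(r.track_id), int(r.partner))
        for r in events_df.itertuples()
    ]
    geometries = {
        int(r.nucleus_id): NucleusGeometry(
            center_y_um=float(r.center_y_um),
            center_x_um=float(r.center_x_um),
            radius_um=float(r.radius_um),
            nucleus_id=int(r.nucleus_id),
        )
        for r in nuclei.itertuples()
    }
    return GroundTruth(tracks=tracks, geometries=geometries, events=events)


# ---------------------------------------------------------------------------
# detections and tracks


def detections_to_csv(detections, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "frame": d.frame,
                "y_um": d.y_um,
                "x_um": d.x_um,
                "peak": d.peak,
                "diameter_um": d.diameter_um,
                "at_border": d.at_border,
                "nucleus_id": -1 if d.nucleus_id is None else d.nucleus_id,
            }
            for d in detections
        ],
        columns=["frame", "y_um", "x_um", "peak", "diameter_um", "at_border", "nucleus_id"],
    ).to_csv(path, index=False)
    return path


def detections_from_csv(path) -> list[Detection]:
    df = pd.read_csv(path)
    return [
        Detection(
            frame=int(r.frame),
            y_um=float(r.y_um),
            x_um=float(r.x_um),
            peak=float(r.peak),
            diameter_um=float(r.diameter_um),
            at_border=bool(r.at_border),
            nucleus_id=None if int(r.nucleus_id) < 0 else int(r.nucleus_id),
        )
        for r in df.itertuples()
    ]


def tracks_to_csv(tracks, path, frame_interval_s: float | None = None) -> Path:
    """Track table: one row per (track, frame) with any fusion/split event."""
    path = Path(path)
    rows = []
    for t in tracks:
        events_by_frame = {e.frame: e for e in t.events}
        for d in t.detections:
            e = events_by_frame.get(d.frame)
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": d.frame,
                    "t_s": None if frame_interval_s is None else d.frame * frame_interval_s,
                    "y_um": d.y_um,
                    "x_um": d.x_um,
                    "diameter_um": d.diameter_um,
                    "peak": d.peak,
                    "event": "" if e is None else f"{e.kind}:{e.partner}",
                }
            )
    pd.DataFrame(
        rows,
        columns=["track_id", "frame", "t_s", "y_um", "x_um", "diameter_um", "peak", "event"],
    ).to_csv(path, index=False)
    return path


def tracks_from_csv(path) -> list[Track]:
    df = pd.read_csv(path, keep_default_na=False)
    tracks = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        t = Track(track_id=int(tid))
        for r in sub.itertuples():
            t.detections.append(
                Detection(
                    frame=int(r.frame),
                    y_um=float(r.y_um),
                    x_um=float(r.x_um),
                    peak=float(r.peak),
                    diameter_um=float(r.diameter_um),
                )
            )
            if r.event:
                kind, partner = str(r.event).split(":")
                t.events.append(TrackEvent(int(r.frame), kind, int(partner)))
        tracks.append(t)
    return tracks
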