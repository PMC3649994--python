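"""Frame-to-frame track linking with gap closing and fusion/split annotation.

Linking solves, for every frame, an optimal assignment between open tracks and
new detections: squared displacement costs, gated at ``max_disp_um`` per frame
of elapsed gap, with a fixed no-link alternative slightly above the gate so
that admissible links are always preferred.  Detections left unmatched start
new tracks; tracks unmatched for more than ``max_gap_frames`` close.  The same
objective is cheap to brute-force on tiny instances, which is how it is
validated.

Fusion and splitting are annotated after the fact: a track that ends right
next to a surviving track is a fusion; a track that appears right next to a
pre-existing one is a split.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .models import ConfigurationError, Detection, Track, TrackEvent

#: Multiplier placing the no-link cost just above the squared gate, so that
#: any admissible link beats leaving both partners unmatched.
_NO_LINK_FACTOR = 1.0001
_BIG = 1e12


def group_by_frame(detections) -> list[tuple[int, list[Detection]]]:
    """Sort detections into per-frame lists ordered by (y, x) for determinism."""
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(int(d.frame), []).append(d)
    out = []
    for f in sorted(by_frame):
        out.append((f, sorted(by_frame[f], key=lambda d: (d.y_um, d.x_um))))
    return out


def frame_assignment(
    track_positions: np.ndarray,
    det_positions: np.ndarray,
    gates_um: np.ndarray,
) -> list[tuple[int, int]]:
    """Optimal gated assignment between open tracks and one frame's detections.

    ``gates_um[i]`` is the per-track gate (``max_disp_um`` times the elapsed
    frame gap).  Returns (track_index, detection_index) links minimizing the
    total squared displacement plus a fixed penalty per unmatched row/column.
    """
    n_t, n_d = len(track_positions), len(det_positions)
    if n_t == 0 or n_d == 0:
        return []
    dist = np.linalg.norm(
        track_positions[:, None, :] - det_positions[None, :, :], axis=2
    )
    allowed = dist <= gates_um[:, None]
    no_link = _NO_LINK_FACTOR * float(np.max(gates_um)) ** 2
    cost = np.full((n_t + n_d, n_t + n_d), 0.0)
    cost[:n_t, :n_d] = np.where(allowed, dist**2, _BIG)
    cost[:n_t, n_d:] = _BIG
    cost[np.arange(n_t), n_d + np.arange(n_t)] = no_link
    cost[n_t:, :n_d] = _BIG
    cost[n_t + np.arange(n_d), np.arange(n_d)] = no_link
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n_t and c < n_d and allowed[r, c]
    ]


def link_tracks(
    detections,
    max_disp_um: float = 1.5,
    max_gap_frames: int = 2,
) -> list[Track]:
    """Link detections (flat iterable or per-frame lists) into tracks.

    ``max_disp_um`` is the per-frame-interval gate; a track may skip up to
    ``max_gap_frames`` frames, with the gate scaled by the elapsed gap.
    Track ids are assigned in order of track birth (frame, then (y, x)).
    """
    if max_disp_um <= 0:
        raise ConfigurationError("max_disp_um must be positive")
    if max_gap_frames < 0:
        raise ConfigurationError("max_gap_frames must be >= 0")
    flat: list[Detection] = []
    for item in detections:
        if isinstance(item, Detection):
            flat.append(item)
        else:
            flat.extend(item)
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    for f, dets in group_by_frame(flat):
        open_tracks = [
            t for t in open_tracks if f - t.end_frame - 1 <= max_gap_frames
        ]
        if open_tracks and dets:
            tpos = np.array([[t.detections[-1].y_um, t.detections[-1].x_um]
                             for t in open_tracks])
            dpos = np.array([[d.y_um, d.x_um] for d in dets])
            gates = np.array([max_disp_um * (f - t.end_frame) for t in open_tracks])
            links = frame_assignment(tpos, dpos, gates)
        else:
            links = []
        matched_dets = set()
        for ti, di in links:
            open_tracks[ti].detections.append(dets[di])
            matched_dets.add(di)
        for di, d in enumerate(dets):
            if di not in matched_dets:
                t = Track(track_id=len(tracks), detections=[d])
                tracks.append(t)
                open_tracks.append(t)
    return tracks


def annotate_fusion_splitting(
    tracks: list[Track],
    merge_dist_um: float = 0.9,
    window_frames: int = 2,
) -> dict[str, int]:
    """Annotate fusion and split events in place; return event counts.

    A track that ends while another track spans the ending frame, with the
    partner passing within ``merge_dist_um``, records a fusion; a track that
    appears next to an already-existing track records a split.  The partner
    distance is taken as the minimum over the partner's detections within
    ``window_frames`` of the event: at the merge frame the single surviving
    detection may be linked to either participant, leaving the other with a
    gap exactly there, and during fast approaches the last co-detection can
    lie well apart while the merged centroid is close.  The default distance
    sits at the optical-merging scale (two spots blur into one blob near
    their joint FWHM), which is when the tracker necessarily drops one of
    them -- well before any true contact distance.
    """
    if merge_dist_um <= 0:
        raise ConfigurationError("merge_dist_um must be positive")
    counts = {"fusion": 0, "split": 0}
    if not tracks:
        return counts
    pos = {t.track_id: {d.frame: d.yx_um for d in t.detections} for t in tracks}
    max_frame = max(t.end_frame for t in tracks)
    for t in tracks:
        t.events = [e for e in t.events if e.kind not in ("fusion", "split")]

    def nearest_partner(t: Track, frame: int, anchor: np.ndarray, spanning: str):
        best: tuple[Track, float] | None = None
        for o in tracks:
            if o is t:
                continue
            if spanning == "continues" and not (o.start_frame <= frame < o.end_frame):
                continue
            if spanning == "preexists" and not (o.start_frame < frame <= o.end_frame):
                continue
            dists = [
                float(np.linalg.norm(anchor - pos[o.track_id][g]))
                for g in range(frame - window_frames, frame + window_frames + 1)
                if g in pos[o.track_id]
            ]
            if dists and (best is None or min(dists) < best[1]):
                best = (o, min(dists))
        return best

    for t in tracks:
        f_end = t.end_frame
        if f_end < max_frame:
            best = nearest_partner(t, f_end, t.detections[-1].yx_um, "continues")
            if best is not None and best[1] <= merge_dist_um:
                t.events.append(TrackEvent(f_end, "fusion", best[0].track_id))
                counts["fusion"] += 1
        f_start = t.start_frame
        if f_start > 0:
            best = nearest_partner(t, f_start, t.detections[0].yx_um, "preexists")
            if best is not None and best[1] <= merge_dist_um:
                t.events.append(TrackEvent(f_start, "split", best[0].track_id))
                counts["split"] += 1
    return counts


def filter_min_length(tracks: list[Track], min_length: int = 10) -> list[Track]:
    """Drop tracks with fewer detections than ``min_length`` (a free parameter)."""
    return [t for t in tracks if len(t) >= min_length]
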