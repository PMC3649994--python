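"""End-to-end orchestration: simulate -> prep -> detect -> track -> kinematics.

A run is described by a single YAML/dict config with per-stage parameter
blocks and a root seed.  Per-condition, per-nucleus movies are simulated (or
loaded), prepared, detected and tracked; kinematics summaries are pooled per
condition.  Every run writes a manifest listing each output file with a
content hash, the seed, and the resolved parameters, so identical
(config, seed) pairs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nio
from .config import MotionModel, SimConfig, get_preset, load_yaml_config
from .detect import detect_movie
from .kinematics import speed_distribution, summarize_nucleus
from .linking import annotate_fusion_splitting, filter_min_length, link_tracks
from .models import ConfigurationError
from .prep import max_project, register_frames, subtract_background_movie
from .simulate import simulate_ne_movie

log = logging.getLogger("netrack")

DEFAULT_STAGES = ("simulate", "prep", "detect", "track", "kinematics")


class PipelineError(RuntimeError):
    """A stage failed; the run halts with a machine-readable error record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.message = message


@dataclass
class RunConfig:
    """Resolved run description (see ``RunConfig.from_dict`` for the YAML shape)."""

    seed: int
    out_dir: Path
    conditions: list[dict]
    stages: tuple[str, ...] = DEFAULT_STAGES
    prep: dict = field(default_factory=dict)
    detect: dict = field(default_factory=dict)
    track: dict = field(default_factory=dict)
    kinematics: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            conditions = d.pop("conditions")
            out_dir = Path(d.pop("out_dir"))
        except KeyError as e:
            raise ConfigurationError(f"run config missing required key: {e}")
        stages = tuple(d.pop("stages", DEFAULT_STAGES))
        unknown = set(stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        cfg = cls(
            seed=int(d.pop("seed", 0)),
            out_dir=out_dir,
            conditions=list(conditions),
            stages=stages,
            prep=d.pop("prep", {}),
            detect=d.pop("detect", {}),
            track=d.pop("track", {}),
            kinematics=d.pop("kinematics", {}),
            log_level=d.pop("log_level", "INFO"),
        )
        if d:
            raise ConfigurationError(f"unknown run config keys: {sorted(d)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(load_yaml_config(path))


def condition_seed(root_seed: int, index: int, nucleus: int = 0) -> int:
    """Deterministic 31-bit sub-seed for (condition, nucleus) substreams."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(index, nucleus))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_condition(cond: dict, root_seed: int, index: int) -> tuple[str, SimConfig, MotionModel]:
    cond = dict(cond)
    name = cond.pop("name", cond.get("preset", f"condition-{index}"))
    preset_name = cond.pop("preset", None)
    overrides = cond.pop("config", {})
    n_nuclei = cond.pop("n_nuclei", None)
    if n_nuclei is not None:
        overrides = {**overrides, "n_nuclei": n_nuclei}
    if preset_name is not None:
        preset = get_preset(preset_name, **overrides)
        sim_cfg, motion = preset.config, preset.motion
    else:
        sim_cfg, motion = SimConfig(**overrides), MotionModel()
    motion = dataclasses.replace(motion, **cond.pop("motion", {}))
    sim_cfg = dataclasses.replace(sim_cfg, seed=condition_seed(root_seed, index))
    if cond:
        raise ConfigurationError(f"unknown condition keys: {sorted(cond)}")
    return str(name), sim_cfg, motion


def run_condition(
    sim_cfg: SimConfig,
    motion: MotionModel,
    prep_params: dict | None = None,
    detect_params: dict | None = None,
    track_params: dict | None = None,
    kin_params: dict | None = None,
):
    """Run the full chain for one condition, one nucleus per movie.

    Returns ``(summaries, tracks_by_nucleus, detections_by_nucleus, gts)``.
    This is the library entry point the numbered analysis scripts and the
    acceptance checks use; file IO lives in :func:`run_pipeline`.
    """
    prep_params = dict(prep_params or {})
    detect_params = dict(detect_params or {})
    track_params = dict(track_params or {})
    kin_params = dict(kin_params or {})
    register = prep_params.pop("register", False)
    dmin, dmax = sim_cfg.aggregate_diameter_um
    detect_params.setdefault("min_diameter_um", max(0.2, 0.7 * dmin))
    detect_params.setdefault("max_diameter_um", 1.1 * dmax)
    detect_params.setdefault("psf_sigma_um", sim_cfg.psf_sigma_um)
    summaries, all_tracks, all_dets, gts = [], [], [], []
    per_nucleus = dataclasses.replace(sim_cfg, n_nuclei=1)
    for k in range(sim_cfg.n_nuclei):
        cfg_k = dataclasses.replace(
            per_nucleus, seed=condition_seed(sim_cfg.seed, 0, nucleus=k)
        )
        movie, gt = simulate_ne_movie(cfg_k, motion)
        proj = max_project(movie)
        bg = subtract_background_movie(proj, **prep_params)
        frames = register_frames(bg).frames if register else bg.data
        dets = detect_movie(frames, cfg_k.pixel_size_um, **detect_params)
        tracks = link_tracks(dets, **track_params)
        annotate_fusion_splitting(tracks)
        geom = gt.geometries[0]
        summaries.append(
            summarize_nucleus(tracks, geom, cfg_k.frame_interval_s, **kin_params)
        )
        all_tracks.append(tracks)
        all_dets.append(dets)
        gts.append(gt)
    return summaries, all_tracks, all_dets, gts


def pool_condition(summaries, tracks_by_nucleus, frame_interval_s: float,
                   min_track_length: int = 10) -> dict:
    """Pool per-nucleus summaries into per-condition statistics."""
    arcs = np.concatenate([s.arcs_deg for s in summaries if not s.empty] or [np.empty(0)])
    kept = [
        t
        for tracks in tracks_by_nucleus
        for t in filter_min_length(tracks, min_track_length)
    ]
    out = {
        "n_nuclei": len(summaries),
        "n_tracks": int(sum(s.n_tracks for s in summaries)),
        "arc_mean_deg": float(arcs.mean()) if arcs.size else float("nan"),
        "arc_max_deg": float(arcs.max()) if arcs.size else float("nan"),
        "arc_min_deg": float(arcs.min()) if arcs.size else float("nan"),
    }
    if kept:
        dist = speed_distribution(kept, frame_interval_s)
        out["fraction_above_40"] = dist.fractions_above[40.0]
        out["fraction_at_or_above_160"] = dist.fractions_above[160.0]
        out["n_intervals"] = dist.n
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write outputs plus a manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "conditions": {},
        "params": {
            "prep": config.prep,
            "detect": config.detect,
            "track": config.track,
            "kinematics": config.kinematics,
        },
    }
    min_len = int(config.kinematics.get("min_track_length", 10))
    for i, cond in enumerate(config.conditions):
        try:
            name, sim_cfg, motion = _resolve_condition(cond, config.seed, i)
        except ConfigurationError:
            raise
        log.info("condition %s: %d nuclei", name, sim_cfg.n_nuclei)
        cdir = out_dir / name
        cdir.mkdir(parents=True, exist_ok=True)
        files: dict[str, str] = {}
        try:
            summaries, tracks_by_nuc, dets_by_nuc, gts = run_condition(
                sim_cfg, motion, config.prep, config.detect, config.track,
                config.kinematics,
            )
        except (ConfigurationError, PipelineError):
            raise
        except Exception as e:  # halt with a machine-readable record
            record = {"condition": name, "error": str(e)}
            (out_dir / "error.json").write_text(json.dumps(record, indent=1))
            raise PipelineError("run_condition", str(e)) from e
        if "simulate" in config.stages:
            for k, gt in enumerate(gts):
                nio.write_ground_truth(cdir, gt, stem=f"gt_n{k:02d}")
            files["ground_truth"] = "per-nucleus gt_n*.csv"
        if "detect" in config.stages:
            for k, dets in enumerate(dets_by_nuc):
                nio.detections_to_csv(dets, cdir / f"detections_n{k:02d}.csv")
        if "track" in config.stages:
            for k, tracks in enumerate(tracks_by_nuc):
                nio.tracks_to_csv(
                    tracks, cdir / f"tracks_n{k:02d}.csv",
                    frame_interval_s=sim_cfg.frame_interval_s,
                )
        pooled = pool_condition(summaries, tracks_by_nuc, sim_cfg.frame_interval_s, min_len)
        summary_path = cdir / "summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "condition": name,
                    "seed": sim_cfg.seed,
                    "pooled": pooled,
                    "per_nucleus": [s.as_dict() for s in summaries],
                },
                indent=1,
                sort_keys=True,
                allow_nan=True,
            )
        )
        hashes = {
            str(p.relative_to(out_dir)): _sha256(p)
            for p in sorted(cdir.glob("*.csv")) + [summary_path]
        }
        manifest["conditions"][name] = {
            "summary": pooled,
            "files": hashes,
            "sim_seed": sim_cfg.seed,
            "frame_interval_s": sim_cfg.frame_interval_s,
            "nucleus_radius_um": sim_cfg.nucleus_radius_um,
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# reporting


def render_report(manifest_path, out_dir=None) -> list[Path]:
    """Render per-condition three-panel movement reports plus a stats table.

    Panels per condition: track displacement map, arc fan (one wedge per
    track), and the pooled projected-speed distribution.  Conditions missing
    kinematics outputs are reported as partial, with a warning in the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Wedge
    import pandas as pd

    manifest_path = Path(manifest_path)
    run_dir = manifest_path.parent
    out_dir = Path(out_dir) if out_dir else run_dir / "report"
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = json.loads(manifest_path.read_text())
    written: list[Path] = []
    rows = []
    for name, entry in manifest["conditions"].items():
        cdir = run_dir / name
        dt = float(entry.get("frame_interval_s", 5.0))
        radius_um = float(entry.get("nucleus_radius_um", 2.0))
        track_files = sorted(cdir.glob("tracks_n*.csv"))
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        fig.suptitle(name)
        summary = entry.get("summary", {})
        rows.append({"condition": name, **summary})
        if not track_files or not summary:
            axes[1].text(0.5, 0.5, "no qualifying tracks", ha="center", va="center")
            log.warning("condition %s: missing tracks; partial report", name)
        else:
            all_tracks = [t for f in track_files for t in nio.tracks_from_csv(f)]
            ax = axes[0]
            for t in all_tracks:
                pos = t.positions_um
                ax.plot(pos[:, 1], pos[:, 0], lw=0.6)
            ax.set_aspect("equal")
            ax.invert_yaxis()
            ax.set_xlabel("x (µm)")
            ax.set_ylabel("y (µm)")
            ax.set_title("displacement tracks")
            ax = axes[1]
            arcs = []
            for t in all_tracks:
                pos = t.positions_um
                if len(pos) >= 10:
                    arcs.append(
                        float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
                    )
            radius = 1.0
            for j, path_um in enumerate(sorted(arcs, reverse=True)):
                deg = path_um / (2 * np.pi * radius_um) * 360.0
                ax.add_patch(
                    Wedge((0, 0), radius - 0.015 * j, 90 - deg / 2, 90 + deg / 2,
                          width=0.012, alpha=0.7)
                )
            ax.set_xlim(-1.1, 1.1)
            ax.set_ylim(-0.2, 1.1)
            ax.set_aspect("equal")
            ax.axis("off")
            ax.set_title("arc coverage")
            ax = axes[2]
            speeds = []
            for t in all_tracks:
                pos = t.positions_um
                if len(pos) >= 2:
                    fr = t.frames
                    d = np.linalg.norm(np.diff(pos, axis=0), axis=1) * 1e3
                    g = np.diff(fr)
                    speeds.extend(d[g == 1] / (g[g == 1] * dt))
            if speeds:
                edges = np.arange(0, 260, 10)
                hist, _ = np.histogram(np.clip(speeds, 0, 255), bins=edges)
                ax.plot(edges[:-1], 100.0 * hist / hist.sum(), drawstyle="steps-post")
            ax.set_xlabel("projected speed (nm/s)")
            ax.set_ylabel("% of intervals")
            ax.set_title("speed distribution")
        fig.tight_layout()
        fig_path = out_dir / f"{name}.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        written.append(fig_path)
    table = out_dir / "summary_table.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    written.append(table)
    return written
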