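"""Seeded synthetic nuclear-envelope movies with known ground truth.

Aggregates live on the surface of a sphere (the nuclear envelope) and move by
alternating processive great-circle runs with diffusive dwells; the analysis
pipeline only ever sees the 2D maximum-intensity projection, so projection
losses are part of the simulation by construction.  Rendering draws each
aggregate as a 3D Gaussian (object size convolved with the PSF), applies an
exponential photobleaching decay, and corrupts the expected image with Poisson
shot noise plus a Gaussian read-noise floor.

Randomness: one root ``numpy.random.SeedSequence`` per movie (``config.seed``)
is spawned into one child stream per nucleus plus one for camera noise, so
nuclei are statistically independent and reproducible in parallel.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .config import MotionModel, SimConfig
from .models import (
    ConfigurationError,
    GroundTruth,
    GroundTruthEvent,
    GroundTruthTrack,
    Movie,
    NucleusGeometry,
)

_RUN, _PAUSE = "run", "pause"


# ---------------------------------------------------------------------------
# motion on the sphere


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_tangent(rng: np.random.Generator, p_hat: np.ndarray) -> np.ndarray:
    v = rng.normal(size=3)
    v -= v.dot(p_hat) * p_hat
    n = np.linalg.norm(v)
    if n < 1e-12:  # pragma: no cover - measure-zero fallback
        v = np.cross(p_hat, [1.0, 0.0, 0.0])
        n = np.linalg.norm(v)
    return v / n


def _state_steps(rng: np.random.Generator, mean_duration_s: float, dt_s: float) -> int:
    """Number of whole steps spent in a state (geometric, mean duration/dt)."""
    if not math.isfinite(mean_duration_s):
        return np.iinfo(np.int32).max
    p = min(1.0, dt_s / max(mean_duration_s, 1e-12))
    return int(rng.geometric(p))


class _Walker:
    """Run/pause walker on a sphere of radius R (µm); one step per frame."""

    def __init__(self, model: MotionModel, radius_um: float, dt_s: float,
                 rng: np.random.Generator, p_hat: np.ndarray | None = None):
        if dt_s <= 0:
            raise ConfigurationError("dt must be positive")
        self.m = model
        self.R = radius_um
        self.dt = dt_s
        self.rng = rng
        self.p_hat = _random_unit(rng) if p_hat is None else p_hat / np.linalg.norm(p_hat)
        self.u = _random_tangent(rng, self.p_hat)
        self._enter_state(_RUN if rng.random() >= model.pause_fraction else _PAUSE)

    def _pause_mean_s(self) -> float:
        pf = self.m.pause_fraction
        if pf >= 1.0:
            return math.inf
        return self.m.run_persistence_s * pf / (1.0 - pf)

    def _enter_state(self, state: str) -> None:
        self.state = state
        if state == _RUN:
            self.u = _random_tangent(self.rng, self.p_hat)
            mean = self.m.run_persistence_s
        else:
            mean = self._pause_mean_s()
        self.steps_left = _state_steps(self.rng, mean, self.dt)

    def step(self) -> None:
        if self.state == _RUN:
            theta = (self.m.run_speed_nm_s * 1e-3) * self.dt / self.R
            p_new = math.cos(theta) * self.p_hat + math.sin(theta) * self.u
            self.u = math.cos(theta) * self.u - math.sin(theta) * self.p_hat
            self.p_hat = p_new / np.linalg.norm(p_new)
        else:
            s = math.sqrt(2.0 * self.m.diffusion_um2_s * self.dt) / self.R
            e2 = np.cross(self.p_hat, self.u)
            xi = self.rng.normal(size=2) * s
            p_new = self.p_hat + xi[0] * self.u + xi[1] * e2
            self.p_hat = p_new / np.linalg.norm(p_new)
            self.u -= self.u.dot(self.p_hat) * self.p_hat
            self.u /= np.linalg.norm(self.u)
        self.steps_left -= 1
        if self.steps_left <= 0:
            if self.state == _RUN and self.m.pause_fraction > 0.0:
                self._enter_state(_PAUSE)
            elif self.state == _PAUSE and self.m.pause_fraction < 1.0:
                self._enter_state(_RUN)
            else:
                self._enter_state(self.state)

    def position_um(self, center_yxz_um: np.ndarray) -> np.ndarray:
        # p_hat is (x, y, z) internally; emit (y, x, z) movie coordinates.
        p = self.R * self.p_hat
        return center_yxz_um + np.array([p[1], p[0], p[2]])


def simulate_motion_track(
    model: MotionModel,
    geometry: NucleusGeometry,
    duration_s: float,
    dt_s: float,
    seed: int | np.random.Generator = 0,
) -> GroundTruthTrack:
    """Simulate one aggregate trajectory on the envelope sphere.

    Returns a ground-truth track with ``duration_s/dt_s + 1`` samples; the
    sphere is centred at the projected nucleus centre with z centred on 0.
    States label the step *leaving* each sample (last state repeated).
    """
    if dt_s <= 0 or duration_s < dt_s:
        raise ConfigurationError("require duration >= dt > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = np.array([geometry.center_y_um, geometry.center_x_um, 0.0])
    walker = _Walker(model, geometry.radius_um, dt_s, rng)
    n_steps = int(round(duration_s / dt_s))
    positions = np.empty((n_steps + 1, 3))
    states = np.empty(n_steps + 1, dtype=object)
    positions[0] = walker.position_um(center)
    for i in range(n_steps):
        states[i] = walker.state
        walker.step()
        positions[i + 1] = walker.position_um(center)
    states[n_steps] = states[n_steps - 1]
    return GroundTruthTrack(
        track_id=0, nucleus_id=geometry.nucleus_id, start_frame=0,
        positions_um=positions, diameters_um=np.full(n_steps + 1, 1.0),
        states=states.astype(str),
    )


def geodesic_path_length(track: GroundTruthTrack, geometry: NucleusGeometry) -> float:
    """Total great-circle path length of a track on its envelope sphere, µm."""
    center = np.array([geometry.center_y_um, geometry.center_x_um, 0.0])
    rel = track.positions_um - center
    r = np.linalg.norm(rel, axis=1)
    unit = rel / r[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", unit[:-1], unit[1:]), -1.0, 1.0)
    return float(np.sum(np.arccos(cosang) * geometry.radius_um))


def mean_step_speed_nm_s(model: MotionModel, dt_s: float) -> float:
    """Closed-form expected per-step speed of the run/pause mixture, nm/s.

    Run steps advance exactly ``run_speed * dt`` along a great circle; pause
    steps are 2D tangent-plane Gaussian displacements whose length is Rayleigh
    with mean ``sqrt(pi * D * dt)``.
    """
    pause_nm_s = math.sqrt(math.pi * model.diffusion_um2_s / dt_s) * 1e3
    pf = model.pause_fraction
    return (1.0 - pf) * model.run_speed_nm_s + pf * pause_nm_s


# ---------------------------------------------------------------------------
# joint per-nucleus simulation with fusion and splitting


class _Aggregate:
    __slots__ = ("track_id", "walker", "diameter", "positions", "diameters",
                 "states", "start_frame")

    def __init__(self, track_id, walker, diameter, start_frame):
        self.track_id = track_id
        self.walker = walker
        self.diameter = diameter
        self.positions: list[np.ndarray] = []
        self.diameters: list[float] = []
        self.states: list[str] = []
        self.start_frame = start_frame

    def record(self, center):
        self.positions.append(self.walker.position_um(center))
        self.diameters.append(self.diameter)
        self.states.append(self.walker.state)

    def finalize(self, nucleus_id) -> GroundTruthTrack:
        return GroundTruthTrack(
            track_id=self.track_id, nucleus_id=nucleus_id,
            start_frame=self.start_frame,
            positions_um=np.array(self.positions),
            diameters_um=np.array(self.diameters),
            states=np.array(self.states, dtype=str),
        )


def simulate_nucleus_tracks(
    model: MotionModel,
    config: SimConfig,
    geometry: NucleusGeometry,
    rng: np.random.Generator,
    first_track_id: int = 0,
) -> tuple[list[GroundTruthTrack], list[GroundTruthEvent]]:
    """Simulate all aggregates of one nucleus jointly, with fusion/splitting.

    Fusion merges the smaller partner into the larger conserving volume;
    splitting divides volume equally and offsets the child past the fusion
    radius.  A short refractory window keeps a freshly split pair from
    flickering straight back into a fusion.
    """
    center = np.array([geometry.center_y_um, geometry.center_x_um, 0.0])
    R = geometry.radius_um
    dt = config.frame_interval_s
    lo, hi = config.aggregates_per_nucleus
    n0 = int(rng.integers(lo, hi + 1))
    next_id = first_track_id
    active: list[_Aggregate] = []
    for _ in range(n0):
        for _attempt in range(64):
            w = _Walker(model, R, dt, rng)
            pos = w.position_um(center)
            # aggregates occupy distinct envelope sites: keep initial
            # placements resolvable and outside the fusion gate
            min_sep = max(1.5 * model.fusion_radius_um, 0.6)
            if all(np.linalg.norm(pos - a.positions[-1]) > min_sep for a in active if a.positions):
                break
        d = float(rng.uniform(*config.aggregate_diameter_um))
        agg = _Aggregate(next_id, w, d, start_frame=0)
        next_id += 1
        agg.record(center)
        active.append(agg)
    done: list[_Aggregate] = []
    events: list[GroundTruthEvent] = []
    refractory: dict[frozenset, int] = {}

    for f in range(1, config.frames):
        for a in active:
            a.walker.step()
            a.record(center)
        # fusion: greedily merge closest admissible pairs
        if model.fusion_radius_um > 0:
            merged = True
            while merged and len(active) > 1:
                merged = False
                best = None
                for i in range(len(active)):
                    for j in range(i + 1, len(active)):
                        a, b = active[i], active[j]
                        key = frozenset((a.track_id, b.track_id))
                        if refractory.get(key, -1) >= f:
                            continue
                        dist = np.linalg.norm(a.positions[-1] - b.positions[-1])
                        if dist <= model.fusion_radius_um and (best is None or dist < best[0]):
                            best = (dist, i, j)
                if best is not None:
                    _, i, j = best
                    a, b = active[i], active[j]
                    survivor, gone = (a, b) if (a.diameter, -a.track_id) >= (b.diameter, -b.track_id) else (b, a)
                    survivor.diameter = (survivor.diameter ** 3 + gone.diameter ** 3) ** (1 / 3)
                    events.append(GroundTruthEvent(f, "fusion", gone.track_id, survivor.track_id))
                    active.remove(gone)
                    done.append(gone)
                    merged = True
        # splitting
        if model.split_rate_per_s > 0:
            p_split = min(1.0, model.split_rate_per_s * dt)
            min_child = 0.9 * config.aggregate_diameter_um[0]
            for a in list(active):
                child_d = a.diameter / 2 ** (1 / 3)
                if child_d < min_child or rng.random() >= p_split:
                    continue
                a.diameter = child_d
                a.diameters[-1] = child_d
                w = _Walker(model, R, dt, rng, p_hat=a.walker.p_hat.copy())
                # place the child just past the fusion gate, along a random tangent
                offset = 1.4 * max(model.fusion_radius_um, 0.15)
                tang = _random_tangent(rng, w.p_hat)
                p_new = w.p_hat + (offset / R) * tang
                w.p_hat = p_new / np.linalg.norm(p_new)
                w.u -= w.u.dot(w.p_hat) * w.p_hat
                w.u /= np.linalg.norm(w.u)
                child = _Aggregate(next_id, w, child_d, start_frame=f)
                next_id += 1
                child.record(center)
                events.append(GroundTruthEvent(f, "split", child.track_id, a.track_id))
                refractory[frozenset((a.track_id, child.track_id))] = f + 5
                active.append(child)
    done.extend(active)
    done.sort(key=lambda a: a.track_id)
    return [a.finalize(geometry.nucleus_id) for a in done], events


# ---------------------------------------------------------------------------
# rendering


def _spot_sigmas_um(config: SimConfig, diameter_um: float) -> tuple[float, float]:
    obj = diameter_um / 2.355  # FWHM-equivalent object sigma
    sxy = math.hypot(config.psf_sigma_um, obj)
    sz = math.hypot(2.5 * config.psf_sigma_um, obj)
    return sxy, sz


def spot_photons(config: SimConfig, diameter_um: float, t_s: float) -> float:
    """Photons emitted per frame: proportional to volume, bleaching exponentially."""
    return (
        config.photon_budget
        * diameter_um ** 3
        * 2.0 ** (-t_s / config.bleach_halflife_s)
    )


def expected_peak_amplitude(config: SimConfig, diameter_um: float, t_s: float = 0.0) -> float:
    """Analytic center-voxel amplitude (above background) of one rendered spot."""
    sxy, sz = _spot_sigmas_um(config, diameter_um)
    sx_px = sxy / config.pixel_size_um
    sz_pl = sz / config.z_spacing_um
    n = spot_photons(config, diameter_um, t_s)
    return n / ((2 * math.pi) ** 1.5 * sx_px ** 2 * sz_pl)


def photon_budget_for_snr(config: SimConfig, snr: float, diameter_um: float) -> float:
    """Photon budget making the initial peak amplitude ``snr`` background sigmas."""
    sigma_bg = math.sqrt(config.background_level + config.noise_floor ** 2)
    base = expected_peak_amplitude(config, diameter_um) / max(config.photon_budget, 1e-12)
    return snr * sigma_bg / (base * 1.0)


def _add_spot(stack: np.ndarray, y_px: float, x_px: float, z_pl: float,
              sxy_px: float, sz_pl: float, photons: float) -> bool:
    """Accumulate a separable 3D Gaussian; returns False if fully out of view."""
    nz, ny, nx = stack.shape
    ry = rx = int(math.ceil(4 * sxy_px))
    rz = int(math.ceil(4 * sz_pl))
    y0, y1 = int(math.floor(y_px)) - ry, int(math.floor(y_px)) + ry + 1
    x0, x1 = int(math.floor(x_px)) - rx, int(math.floor(x_px)) + rx + 1
    z0, z1 = int(math.floor(z_pl)) - rz, int(math.floor(z_pl)) + rz + 1
    cy0, cy1 = max(y0, 0), min(y1, ny)
    cx0, cx1 = max(x0, 0), min(x1, nx)
    cz0, cz1 = max(z0, 0), min(z1, nz)
    if cy0 >= cy1 or cx0 >= cx1 or cz0 >= cz1:
        return False
    ys = np.arange(cy0, cy1)
    xs = np.arange(cx0, cx1)
    zs = np.arange(cz0, cz1)
    gy = np.exp(-0.5 * ((ys - y_px) / sxy_px) ** 2) / (math.sqrt(2 * math.pi) * sxy_px)
    gx = np.exp(-0.5 * ((xs - x_px) / sxy_px) ** 2) / (math.sqrt(2 * math.pi) * sxy_px)
    gz = np.exp(-0.5 * ((zs - z_pl) / sz_pl) ** 2) / (math.sqrt(2 * math.pi) * sz_pl)
    stack[cz0:cz1, cy0:cy1, cx0:cx1] += photons * (
        gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )
    return 0 <= y_px < ny and 0 <= x_px < nx


def render_expected(config: SimConfig, gt: GroundTruth, shape_yx: tuple[int, int]) -> np.ndarray:
    """Noise-free expected photon stack (frames, z, y, x) for a ground truth."""
    nz = config.z_planes
    expected = np.full((config.frames, nz, *shape_yx), config.background_level, dtype=np.float64)
    z_mid = (nz - 1) / 2.0
    clipped = False
    for track in gt.tracks:
        sxy_um, sz_um = None, None
        last_d = None
        for i, f in enumerate(track.frames):
            d = float(track.diameters_um[i])
            if d != last_d:
                sxy_um, sz_um = _spot_sigmas_um(config, d)
                last_d = d
            y, x, z = track.positions_um[i]
            ok = _add_spot(
                expected[f],
                y / config.pixel_size_um,
                x / config.pixel_size_um,
                z / config.z_spacing_um + z_mid,
                sxy_um / config.pixel_size_um,
                sz_um / config.z_spacing_um,
                spot_photons(config, d, f * config.frame_interval_s),
            )
            clipped |= not ok
    if clipped:
        warnings.warn("some aggregates fell outside the field of view and were clipped")
    return expected


def simulate_ne_movie(
    config: SimConfig,
    model: MotionModel,
    *,
    shot_noise: bool = True,
) -> tuple[Movie, GroundTruth]:
    """Simulate a calibrated z-stack movie plus its ground truth.

    Nuclei are laid out on a grid of square per-nucleus fields; motion,
    fusion/splitting and rendering follow the module docstring.  Passing
    ``shot_noise=False`` keeps the expected image (plus any Gaussian floor),
    which is useful for noise-free oracles.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_nuclei + 1)
    noise_rng = np.random.default_rng(streams[-1])

    fov = config.fov_px
    cols = max(1, int(math.ceil(math.sqrt(max(config.n_nuclei, 1)))))
    rows = max(1, int(math.ceil(max(config.n_nuclei, 1) / cols)))
    shape_yx = (rows * fov, cols * fov)

    tracks: list[GroundTruthTrack] = []
    events: list[GroundTruthEvent] = []
    geometries: dict[int, NucleusGeometry] = {}
    next_track = 0
    for n in range(config.n_nuclei):
        r, c = divmod(n, cols)
        geom = NucleusGeometry(
            center_y_um=(r + 0.5) * fov * config.pixel_size_um,
            center_x_um=(c + 0.5) * fov * config.pixel_size_um,
            radius_um=config.nucleus_radius_um,
            nucleus_id=n,
        )
        geometries[n] = geom
        rng = np.random.default_rng(streams[n])
        ntracks, nevents = simulate_nucleus_tracks(model, config, geom, rng, next_track)
        next_track = max([next_track] + [t.track_id + 1 for t in ntracks])
        tracks.extend(ntracks)
        events.extend(nevents)
    gt = GroundTruth(tracks=tracks, geometries=geometries, events=events)

    expected = render_expected(config, gt, shape_yx)
    if shot_noise:
        data = noise_rng.poisson(expected).astype(np.float32)
    else:
        data = expected.astype(np.float32)
    if config.noise_floor > 0:
        data = data + noise_rng.normal(0.0, config.noise_floor, size=data.shape).astype(np.float32)
    np.clip(data, 0.0, None, out=data)
    movie = Movie(
        data=data,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
        z_spacing_um=config.z_spacing_um,
    )
    return movie, gt
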