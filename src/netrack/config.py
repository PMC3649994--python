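"""Simulation configuration: motion models, acquisition geometry, presets.

The default acquisition geometry mirrors the live-imaging setup the analyses
assume: 1 µm-spaced z-stacks acquired every 5 s over 15 min (181 frames), at
~0.107 µm/px.  Presets describe three qualitative movement regimes of
chromosome-end (SUN-1) aggregates on the nuclear envelope:

``wt-like``
    few large patches, mostly processive dynein-driven runs (~190 nm/s);
``spd3-like``
    many small foci, rare short runs on a slow diffusive background;
``jf18-like``
    near-pure slow diffusion, no motor-driven runs.

Preset parameter values are this package's own calibration, chosen so the
qualitative ordering wt > spd3 > jf18 in mobility statistics holds; they are
not measured constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .models import ConfigurationError

#: Average speed of dynein-driven SUN-1/ZYG-12 aggregate movement, nm/s.
DYNEIN_RUN_SPEED_NM_S = 190.0


@dataclass
class MotionModel:
    """Two-state (run / pause) motion of an aggregate on the envelope sphere.

    Parameters
    ----------
    run_speed_nm_s:
        Mean speed during processive runs, nm/s.
    run_persistence_s:
        Mean run duration, s.  Pause durations are scaled so that the
        long-run fraction of time spent paused equals ``pause_fraction``.
    diffusion_um2_s:
        Surface diffusion coefficient during pauses, µm²/s.
    pause_fraction:
        Stationary fraction of time spent in the pause state, in [0, 1].
    fusion_radius_um:
        3D distance below which two aggregates merge.  0 disables fusion.
    split_rate_per_s:
        Per-aggregate rate of splitting into two, events/s.
    """

    run_speed_nm_s: float = DYNEIN_RUN_SPEED_NM_S
    run_persistence_s: float = 20.0
    diffusion_um2_s: float = 2e-4
    pause_fraction: float = 0.35
    fusion_radius_um: float = 0.0
    split_rate_per_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("run_speed_nm_s", "run_persistence_s", "diffusion_um2_s",
                     "fusion_radius_um", "split_rate_per_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.pause_fraction <= 1.0:
            raise ConfigurationError("pause_fraction must lie in [0, 1]")


@dataclass
class SimConfig:
    """Acquisition geometry and rendering parameters for synthetic movies."""

    n_nuclei: int = 1
    nucleus_radius_um: float = 2.0
    aggregates_per_nucleus: tuple[int, int] = (2, 4)  # inclusive range
    aggregate_diameter_um: tuple[float, float] = (1.2, 1.8)
    frames: int = 181
    frame_interval_s: float = 5.0
    z_planes: int = 7
    z_spacing_um: float = 1.0
    pixel_size_um: float = 0.107
    psf_sigma_um: float = 0.2
    photon_budget: float = 12000.0  # photons/frame for a 1 µm reference aggregate
    bleach_halflife_s: float = 900.0
    background_level: float = 10.0  # mean background photons per voxel
    noise_floor: float = 2.0  # Gaussian read-noise sigma, counts
    margin_um: float = 1.2  # field margin around the projected nucleus
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.aggregates_per_nucleus, int):
            self.aggregates_per_nucleus = (self.aggregates_per_nucleus,) * 2
        else:
            self.aggregates_per_nucleus = tuple(self.aggregates_per_nucleus)
        self.aggregate_diameter_um = tuple(self.aggregate_diameter_um)
        if self.frames < 2:
            raise ConfigurationError("frames must be >= 2")
        for name in ("nucleus_radius_um", "frame_interval_s", "z_spacing_um",
                     "pixel_size_um", "psf_sigma_um", "bleach_halflife_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_nuclei < 0 or self.z_planes < 1:
            raise ConfigurationError("n_nuclei must be >= 0 and z_planes >= 1")
        if self.aggregates_per_nucleus[0] < 0 or (
            self.aggregates_per_nucleus[1] < self.aggregates_per_nucleus[0]
        ):
            raise ConfigurationError("invalid aggregates_per_nucleus range")
        if self.aggregate_diameter_um[0] <= 0 or (
            self.aggregate_diameter_um[1] < self.aggregate_diameter_um[0]
        ):
            raise ConfigurationError("invalid aggregate_diameter_um range")
        if self.photon_budget < 0 or self.background_level < 0 or self.noise_floor < 0:
            raise ConfigurationError("photon counts and noise terms must be >= 0")

    @property
    def fov_px(self) -> int:
        """Side of one per-nucleus field, px (covers the projected nucleus plus margin)."""
        side = (2.0 * self.nucleus_radius_um + 2.0 * self.margin_um) / self.pixel_size_um
        return int(-(-side // 8) * 8)  # round up to a multiple of 8

    @property
    def duration_s(self) -> float:
        return (self.frames - 1) * self.frame_interval_s


@dataclass
class Preset:
    motion: MotionModel
    config: SimConfig


def _preset_table() -> dict[str, Preset]:
    return {
        "wt-like": Preset(
            motion=MotionModel(
                run_speed_nm_s=DYNEIN_RUN_SPEED_NM_S,
                run_persistence_s=20.0,
                diffusion_um2_s=2e-4,
                pause_fraction=0.35,
                fusion_radius_um=0.45,
                split_rate_per_s=0.008,
            ),
            config=SimConfig(
                aggregates_per_nucleus=(2, 4),
                aggregate_diameter_um=(1.2, 1.8),
                photon_budget=48000.0,
            ),
        ),
        "spd3-like": Preset(
            motion=MotionModel(
                run_speed_nm_s=DYNEIN_RUN_SPEED_NM_S,
                run_persistence_s=5.0,
                diffusion_um2_s=2e-4,
                pause_fraction=0.8,
                fusion_radius_um=0.2,
                split_rate_per_s=0.001,
            ),
            config=SimConfig(
                aggregates_per_nucleus=(6, 10),
                aggregate_diameter_um=(0.5, 0.9),
                photon_budget=48000.0,
            ),
        ),
        # same optical scene as spd3-like (many small foci) so that arc
        # statistics compare motion, not detectability; only the motion
        # differs: no motor-driven runs, slower diffusion.
        "jf18-like": Preset(
            motion=MotionModel(
                run_speed_nm_s=0.0,
                run_persistence_s=10.0,
                diffusion_um2_s=5e-5,
                pause_fraction=1.0,
                fusion_radius_um=0.0,
                split_rate_per_s=0.0,
            ),
            config=SimConfig(
                aggregates_per_nucleus=(6, 10),
                aggregate_diameter_um=(0.5, 0.9),
                photon_budget=48000.0,
            ),
        ),
    }


PRESET_NAMES = tuple(_preset_table())


def get_preset(name: str, *, seed: int | None = None, **config_overrides) -> Preset:
    """Return a fresh ``Preset`` by name, optionally overriding config fields."""
    table = _preset_table()
    if name not in table:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    preset = table[name]
    cfg = dataclasses.replace(preset.config, **config_overrides)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return Preset(motion=preset.motion, config=cfg)


@dataclass
class CytoSimConfig:
    """Generator settings for synthetic cytology score tables.

    ``foci_count_dist`` maps a category (``"focus"``/``"patch"``) to per-zone
    categorical distributions ``(values, probabilities)`` over per-nucleus
    counts; a single distribution is broadcast over zones.
    """

    chiasma_prob: float = 0.95
    n_oocytes: int = 52
    pairing_prob_by_zone: tuple[float, ...] = (0.35, 0.90, 0.93, 0.95, 0.95)
    n_nuclei_per_zone: int = 100
    foci_count_dist: dict = field(default_factory=dict)
    chromosome_number: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chiasma_prob <= 1.0:
            raise ConfigurationError("chiasma_prob must lie in [0, 1]")
        self.pairing_prob_by_zone = tuple(self.pairing_prob_by_zone)
        if any(not 0.0 <= p <= 1.0 for p in self.pairing_prob_by_zone):
            raise ConfigurationError("pairing probabilities must lie in [0, 1]")
        if self.n_oocytes < 0 or self.n_nuclei_per_zone < 0:
            raise ConfigurationError("sample sizes must be >= 0")
        if self.chromosome_number <= 0 or self.chromosome_number % 2:
            raise ConfigurationError("chromosome_number must be a positive even 2n")

    @property
    def n_zones(self) -> int:
        return len(self.pairing_prob_by_zone)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return data


def sim_config_from_dict(d: dict) -> tuple[SimConfig, MotionModel]:
    """Build (SimConfig, MotionModel) from a parsed YAML block.

    A ``preset`` key seeds both; explicit ``config``/``motion`` blocks override
    individual fields.
    """
    d = dict(d)
    preset_name = d.pop("preset", None)
    if preset_name is not None:
        preset = get_preset(preset_name)
        cfg, motion = preset.config, preset.motion
    else:
        cfg, motion = SimConfig(), MotionModel()
    cfg = dataclasses.replace(cfg, **d.pop("config", {}))
    motion = dataclasses.replace(motion, **d.pop("motion", {}))
    if d:
        raise ConfigurationError(f"unknown simulation config keys: {sorted(d)}")
    return cfg, motion
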