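"""Projection, background reduction and drift correction of z-stack movies.

The preparation chain mirrors the standard live-imaging workflow: per-frame
maximum-intensity projection of the z-stack, subtraction of a smooth
large-scale background estimate, and translational registration of every
projected frame against frame 0 (a fixed reference avoids drift accumulation
over short movies).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .models import AlignedMovie, ConfigurationError, Movie


def max_project(movie: Movie) -> Movie:
    """Per-frame maximum-intensity projection along z.

    A movie that is already 2D is returned unchanged (with a warning):
    projection is idempotent.
    """
    if not movie.has_z:
        warnings.warn("movie has no z axis; max_project is the identity")
        return movie
    return Movie(
        data=movie.data.max(axis=1),
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )


def subtract_background(
    frame: np.ndarray,
    pixel_size_um: float,
    radius_um: float = 2.0,
    spot_diameter_um: float | None = None,
) -> np.ndarray:
    """Subtract a large-Gaussian background estimate, clipping at zero.

    ``radius_um`` is the Gaussian sigma of the background model and must be
    well above the spot scale so that spots leak only marginally into the
    estimate (leakage ~ (spot sigma / radius)^2).
    """
    if radius_um <= 0 or pixel_size_um <= 0:
        raise ConfigurationError("radius_um and pixel_size_um must be positive")
    if spot_diameter_um is not None and radius_um <= spot_diameter_um:
        raise ConfigurationError(
            f"background radius {radius_um} µm must exceed the expected spot "
            f"diameter {spot_diameter_um} µm"
        )
    frame = np.asarray(frame, dtype=float)
    background = ndimage.gaussian_filter(frame, sigma=radius_um / pixel_size_um)
    return np.clip(frame - background, 0.0, None)


def subtract_background_movie(movie: Movie, radius_um: float = 2.0,
                              spot_diameter_um: float | None = None) -> Movie:
    """Apply :func:`subtract_background` to every frame of a 2D movie."""
    if movie.has_z:
        raise ConfigurationError("background subtraction expects a projected movie")
    data = np.stack([
        subtract_background(f, movie.pixel_size_um, radius_um, spot_diameter_um)
        for f in movie.data
    ])
    return Movie(data, movie.pixel_size_um, movie.frame_interval_s)


def register_frames(
    frames: np.ndarray | Movie,
    upsample_factor: int = 20,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> AlignedMovie:
    """Estimate per-frame translation against frame 0 and resample.

    ``shifts[i]`` is the (dy, dx) displacement of frame ``i``'s content
    relative to frame 0 (a feature at ``(y, x)`` in frame 0 sits at
    ``(y + dy, x + dx)`` in frame ``i``); frames are resampled by the inverse
    shift.  Subpixel precision comes from upsampled phase cross-correlation;
    pass ``upsample_factor=1`` for integer-only alignment.
    """
    if isinstance(frames, Movie):
        if frames.has_z:
            raise ConfigurationError("register projected (2D) movies only")
        pixel_size_um = frames.pixel_size_um
        frame_interval_s = frames.frame_interval_s
        frames = frames.data
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ConfigurationError("registration requires >= 2 2D frames")
    ref = frames[0]
    shifts = np.zeros((frames.shape[0], 2))
    aligned = np.empty_like(frames)
    aligned[0] = ref
    for i in range(1, frames.shape[0]):
        if not np.any(frames[i]) or not np.any(ref):
            warnings.warn(f"frame {i}: all-zero image, assuming zero shift")
            shift = np.zeros(2)
        else:
            # phase_cross_correlation returns the shift that maps the moving
            # image onto the reference, i.e. minus the content displacement.
            shift, _, _ = phase_cross_correlation(
                ref, frames[i], upsample_factor=upsample_factor, normalization=None
            )
            shift = -np.asarray(shift)
        shifts[i] = shift
        if np.allclose(shift % 1.0, 0.0):
            aligned[i] = np.roll(frames[i], (-shift).astype(int), axis=(0, 1))
        else:
            aligned[i] = ndimage.shift(frames[i], -shift, order=3, mode="constant", cval=0.0)
    return AlignedMovie(
        frames=aligned,
        shifts=shifts,
        pixel_size_um=pixel_size_um if pixel_size_um is not None else 1.0,
        frame_interval_s=frame_interval_s if frame_interval_s is not None else 1.0,
    )
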