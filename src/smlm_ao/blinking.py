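"""Synthetic single-molecule blinking frames and acquisition-side processing.

Generates biplane camera frames with stochastically blinking emitters under a
shared wavefront distortion (Poisson emitter counts, exponential photon
budgets, uniform axial positions, Poisson shot noise on every pixel), and
implements the processing applied to real acquisitions before wavefront
inference: temporal-median background estimation, local-maximum subregion
segmentation, isolation filtering and a photon-count threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import EmitterState, OpticalConfig, PupilFunction, _render_planes

__all__ = [
    "AcquisitionConfig",
    "Frame",
    "SubRegion",
    "sample_emitters",
    "simulate_frames",
    "temporal_median_background",
    "segment_subregions",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition statistics and segmentation parameters.

    Defaults reproduce the simulated acquisition protocol: 128x128-pixel
    frames, 13 emitters per frame on average (Poisson), axial positions
    uniform in -1..1 um, exponentially distributed photon budgets of mean
    2,500, 10 background photons per pixel, and a 1,500-photon threshold on
    segmented subregions.
    """

    frame_size: int = 128              # pixels per side
    mean_emitters: float = 13.0        # expected emitters per frame
    z_range: tuple[float, float] = (-1000.0, 1000.0)   # nm, uniform
    mean_photons: float = 2500.0       # exponential mean, photons per emitter
    background: float = 10.0           # background photons per pixel
    frames_per_cycle: int = 20         # frames acquired between mirror updates
    photon_threshold: float = 1500.0   # minimum subregion photons
    subregion_size: int = 32           # crop side (pixels)
    isolation_radius: float = 16.0     # min centre-to-centre distance (pixels)
    detect_sigma: float = 1.0          # Gaussian smoothing before peak search
    detect_threshold: float = 12.0     # peak height above background (photons)

    def __post_init__(self) -> None:
        for name in ("frame_size", "mean_emitters", "mean_photons",
                     "frames_per_cycle", "photon_threshold", "subregion_size",
                     "isolation_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.subregion_size % 2:
            raise ValueError("subregion_size must be even")
        if self.isolation_radius < self.subregion_size / 2:
            raise ValueError("isolation_radius must be >= subregion_size / 2")


@dataclass
class Frame:
    """One acquired biplane frame plus the simulation ground truth."""

    pixels: np.ndarray                 # (2, H, W) integer photon counts
    truth: list[EmitterState] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.pixels < 0):
            raise ValueError("photon counts must be non-negative")


@dataclass
class SubRegion:
    """Background-subtracted biplane crop around one detected emission."""

    images: np.ndarray                 # (2, S, S) photons after subtraction
    center: tuple[int, int]            # (row, col) in the parent frame
    total_photons: float


# ---------------------------------------------------------------------------
# emitter sampling and frame synthesis
# ---------------------------------------------------------------------------

def sample_emitters(config: AcquisitionConfig, optics: OpticalConfig,
                    rng: np.random.Generator) -> list[EmitterState]:
    """Draw one frame's emitters: Poisson count, uniform x/y/z, exp photons."""
    count = int(rng.poisson(config.mean_emitters))
    half = 0.5 * config.frame_size * optics.pixel_size
    out = []
    for _ in range(count):
        out.append(EmitterState(
            x=float(rng.uniform(-half, half)),
            y=float(rng.uniform(-half, half)),
            z=float(rng.uniform(*config.z_range)),
            photons=float(rng.exponential(config.mean_photons)),
            background=0.0,
        ))
    return out


def simulate_frames(true_wavefront: np.ndarray, n_frames: int,
                    config: AcquisitionConfig, optics: OpticalConfig,
                    rng: np.random.Generator,
                    pupil: PupilFunction | None = None,
                    z_offset: float = 0.0) -> list[Frame]:
    """Simulate blinking frames under a shared pupil-phase distortion.

    Each frame draws fresh emitters, accumulates their expected biplane
    images plus the constant background, and applies Poisson shot noise.
    ``z_offset`` shifts every emitter axially (uncompensated focal shift).
    """
    if pupil is None:
        pupil = PupilFunction.flat(optics)
    pupil_field = pupil.complex_field()
    per_frame = [sample_emitters(config, optics, rng) for _ in range(n_frames)]
    all_em = [em for ems in per_frame for em in ems]
    h = config.frame_size
    expected = np.full((n_frames, 2, h, h), float(config.background))
    if all_em:
        # one batched FFT render for every emitter of every frame
        px = optics.pixel_size
        n = optics.pupil_grid
        xyz = np.empty((len(all_em), 3))
        cols = np.empty(len(all_em), dtype=int)
        rows = np.empty(len(all_em), dtype=int)
        for i, em in enumerate(all_em):
            c = int(np.round(em.x / px))
            r = int(np.round(em.y / px))
            cols[i], rows[i] = c, r
            xyz[i] = (em.x - c * px, em.y - r * px, em.z + z_offset)
        patches = _render_planes(pupil_field, true_wavefront, xyz, optics, n,
                                 single_precision=True)
        patches *= np.array([em.photons for em in all_em])[:, None, None, None] / 2.0
        frame_idx = np.concatenate([np.full(len(ems), f, dtype=int)
                                    for f, ems in enumerate(per_frame)])
        half_patch, cc = n // 2, h // 2
        for i in range(len(all_em)):
            r0 = cc + rows[i] - half_patch
            c0 = cc + cols[i] - half_patch
            rs, re = max(r0, 0), min(r0 + n, h)
            cs, ce = max(c0, 0), min(c0 + n, h)
            if rs >= re or cs >= ce:
                continue
            expected[frame_idx[i], :, rs:re, cs:ce] += \
                patches[i, :, rs - r0:re - r0, cs - c0:ce - c0]
    pixels = rng.poisson(expected)
    return [Frame(pixels=pixels[f], truth=per_frame[f])
            for f in range(n_frames)]


# ---------------------------------------------------------------------------
# background estimation and subregion segmentation
# ---------------------------------------------------------------------------

def temporal_median_background(frames: list[Frame], window: int) -> np.ndarray:
    """Per-pixel temporal median over a window of frames.

    Sparse, short-lived emitters are rejected by the median, leaving the
    structured (here: constant) background.  The window must be odd so the
    median is an observed value.
    """
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    if window > len(frames):
        raise ValueError("median window exceeds the number of frames")
    stack = np.stack([f.pixels for f in frames[:window]])
    return np.median(stack, axis=0)


def segment_subregions(frame: Frame, background: np.ndarray,
                       config: AcquisitionConfig) -> list[SubRegion]:
    """Detect isolated single-molecule subregions in one frame.

    Local maxima of the Gaussian-smoothed, background-subtracted,
    plane-summed image are candidate centres.  Candidates closer than the
    isolation radius to another candidate are all discarded (overlapping
    emissions), crops clipped by the frame border are discarded, and crops
    whose background-subtracted photon sum falls below the photon threshold
    are discarded.
    """
    if background.shape != frame.pixels.shape:
        raise ValueError("background shape must match the frame")
    sub = frame.pixels.astype(float) - background
    detect = ndimage.gaussian_filter(sub.sum(axis=0), config.detect_sigma)
    # local maxima above threshold
    footprint = np.ones((3, 3), bool)
    maxima = (detect == ndimage.maximum_filter(detect, footprint=footprint))
    maxima &= detect > config.detect_threshold
    peaks = np.argwhere(maxima)
    if peaks.size == 0:
        return []
    # isolation: discard every member of any close pair
    d2 = ((peaks[:, None, :] - peaks[None, :, :]) ** 2).sum(axis=2).astype(float)
    np.fill_diagonal(d2, np.inf)
    isolated = d2.min(axis=1) >= config.isolation_radius ** 2
    s = config.subregion_size
    h = frame.pixels.shape[-1]
    out = []
    for (r, c), ok in zip(peaks, isolated):
        if not ok:
            continue
        r0, c0 = r - s // 2, c - s // 2
        if r0 < 0 or c0 < 0 or r0 + s > h or c0 + s > h:
            continue
        crop = sub[:, r0:r0 + s, c0:c0 + s]
        total = float(crop.sum())
        if total < config.photon_threshold:
            continue
        out.append(SubRegion(images=crop.copy(), center=(int(r), int(c)),
                             total_photons=total))
    return out
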