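"""Learned wavefront inference from single-molecule emission patterns.

Covers the full estimation side of the closed loop: synthesis of training
pairs from random mirror-mode combinations, the residual CNN regressor that
maps a biplane subregion to mode amplitudes, the small/medium/large-range
network ensemble with uncertainty-based switching, aggregation of
per-subregion inferences into a measurement with standard errors, the
Gerchberg-Saxton phase-retrieval baseline, and the bead-stack procedure that
measures mirror deformation modes from +-unit mirror pokes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.fft as _fft
from scipy import ndimage
from skimage.restoration import unwrap_phase

from .blinking import SubRegion
from .nn import Adam, ConvNet
from .optics import (ModeBasis, OpticalConfig, PSFStack, PupilFunction,
                     WavefrontCoefficients, _render_planes, compose_wavefront,
                     defocus_phase, render_bead_stack)

__all__ = [
    "TrainingConfig",
    "NetworkEnsemble",
    "WavefrontEstimate",
    "InsufficientDetections",
    "generate_training_set",
    "build_network",
    "train_network",
    "estimate_wavefront",
    "characterize_response",
    "phase_retrieve",
    "measure_mirror_modes",
    "normalize_crops",
]


class InsufficientDetections(RuntimeError):
    """Raised when fewer than two usable subregions are available."""


@dataclass
class TrainingConfig:
    """Sampling ranges for training-pair synthesis.

    ``amplitude_range`` is the interval of total distortion W_rms (radians)
    covered by one network; photon / background / z ranges match the
    acquisition statistics the network will see at inference time.
    """

    n_samples: int = 20_000
    amplitude_range: tuple[float, float] = (0.0, 0.8)
    photon_range: tuple[float, float] = (1_000.0, 8_000.0)
    background_range: tuple[float, float] = (2.0, 20.0)
    z_range: tuple[float, float] = (-1_000.0, 1_000.0)
    xy_jitter: float = 1.0             # uniform sub-pixel offset (pixels)
    subregion_size: int = 32
    # crops are centred on the smoothed intensity peak, exactly as the
    # frame segmentation centres its subregions (critical at high
    # aberration, where the brightest lobe sits away from the emitter)
    center_on_peak: bool = True
    render_margin: int = 8             # extra pixels rendered for re-centring
    detect_sigma: float = 1.0          # smoothing before the peak search
    # emulate the acquisition-side selection: only crops that the frame
    # segmentation would accept (peak height and photon sum) are kept, so
    # the training population matches the detected population
    detect_threshold: float | None = 12.0
    photon_threshold: float | None = 1500.0
    max_redraws: int = 20
    # "scene" sampling renders small blinking frames at the acquisition
    # emitter density and segments them with the same detector used at
    # inference time, so the training crops carry the identical selection
    # effects and neighbour-overlap statistics as the closed loop;
    # "isolated" renders one emitter per crop (cheaper, cleaner)
    sampling: str = "scene"
    scene_size: int = 96               # mini-frame side (pixels)
    emitter_density: float = 13.0 / 128 ** 2   # emitters per pixel^2
    mean_photons: float = 2500.0       # exponential mean in scene mode
    max_crops_per_scene: int = 3
    baseline_wavefront: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_range
        if not (0.0 <= lo <= hi <= 3.5):
            raise ValueError("amplitude_range must lie within [0, 3.5]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class WavefrontEstimate:
    """Aggregated network measurement over the subregions of one cycle."""

    mean: WavefrontCoefficients
    stderr: np.ndarray                 # per-mode standard error
    n_subregions: int
    network_id: int

    def __post_init__(self) -> None:
        if self.n_subregions < 2:
            raise ValueError("an estimate requires at least two subregions")
        if np.any(self.stderr < 0):
            raise ValueError("standard errors must be non-negative")

    def magnitude(self) -> float:
        return self.mean.norm()

    def uncertainty(self) -> float:
        return float(np.linalg.norm(self.stderr))


@dataclass
class NetworkEnsemble:
    """Ordered small/medium/large-range regressors with their ranges."""

    networks: list[ConvNet]
    ranges: list[tuple[float, float]]
    basis_id: str = ""

    def __post_init__(self) -> None:
        if len(self.networks) != len(self.ranges):
            raise ValueError("one amplitude range per network is required")
        uppers = [r[1] for r in self.ranges]
        if any(b <= a for a, b in zip(uppers, uppers[1:])):
            raise ValueError("network ranges must be strictly increasing")

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, net in enumerate(self.networks):
            net.save(directory / f"network_{i}.npz")
        meta = {"ranges": [list(r) for r in self.ranges],
                "basis_id": self.basis_id}
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "NetworkEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        nets = [ConvNet.load(directory / f"network_{i}.npz")
                for i in range(len(meta["ranges"]))]
        return cls(networks=nets, ranges=[tuple(r) for r in meta["ranges"]],
                   basis_id=meta.get("basis_id", ""))


# ---------------------------------------------------------------------------
# training data
# ---------------------------------------------------------------------------

def normalize_crops(images: np.ndarray) -> np.ndarray:
    """Photon-scale normalization applied identically in training & inference.

    Each background-subtracted biplane crop is divided by its total photon
    count (floored at 1 to avoid division blow-ups); the background is not
    re-added.
    """
    x = np.asarray(images, dtype=np.float32)
    totals = x.sum(axis=(1, 2, 3), keepdims=True)
    return x / np.maximum(totals, 1.0)


def generate_training_set(basis: ModeBasis, tconfig: TrainingConfig,
                          optics: OpticalConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize (normalized biplane crop, coefficient label) pairs.

    Coefficient directions are uniform on the unit sphere of the mode space
    and total W_rms is uniform in the network's amplitude range; the static
    instrument baseline (if any) is added to the rendered wavefront but
    excluded from the label.  Emitter nuisance parameters (z, photons,
    background, sub-pixel x/y) are drawn from the configured ranges and
    Poisson noise is applied.
    """
    if rng is None:
        rng = np.random.default_rng(tconfig.seed)
    k = basis.n_modes
    n = tconfig.n_samples
    s = tconfig.subregion_size
    lo, hi = tconfig.amplitude_range
    px = optics.pixel_size

    dirs = rng.standard_normal((n, k))
    dirs /= np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-12)
    amps = rng.uniform(lo, hi, size=n)
    labels = dirs * amps[:, None]

    baseline = (tconfig.baseline_wavefront if tconfig.baseline_wavefront
                is not None else 0.0)
    pupil_field = PupilFunction.flat(optics).complex_field()
    images = np.empty((n, 2, s, s), dtype=np.float32)
    if tconfig.sampling == "scene":
        _fill_scene_crops(images, labels, basis, tconfig, optics, rng,
                          baseline)
    elif tconfig.sampling == "isolated":
        for i in range(n):
            phase = compose_wavefront(labels[i], basis) + baseline
            images[i] = _isolated_crop(phase, tconfig, optics, pupil_field,
                                       rng)
    else:
        raise ValueError(f"unknown sampling mode {tconfig.sampling!r}")
    return normalize_crops(images), labels.astype(np.float32)


def _isolated_crop(phase: np.ndarray, tconfig: TrainingConfig,
                   optics: OpticalConfig, pupil_field: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One single-emitter crop, peak-centred and selection-filtered."""
    s = tconfig.subregion_size
    px = optics.pixel_size
    margin = tconfig.render_margin if tconfig.center_on_peak else 0
    render = min(s + 2 * margin, optics.pupil_grid)
    margin = (render - s) // 2
    crop = None
    for _ in range(max(tconfig.max_redraws, 1)):
        xy = rng.uniform(-tconfig.xy_jitter, tconfig.xy_jitter, size=2) * px
        z = rng.uniform(*tconfig.z_range)
        photons = rng.uniform(*tconfig.photon_range)
        bg = rng.uniform(*tconfig.background_range)
        patch = _render_planes(pupil_field, phase,
                               np.array([[xy[0], xy[1], z]]), optics,
                               render, single_precision=True)[0]
        noisy = rng.poisson(patch * (photons / 2.0) + bg
                            ).astype(np.float32) - bg
        if margin:
            det = ndimage.gaussian_filter(noisy.sum(axis=0),
                                          tconfig.detect_sigma)
            r, c = np.unravel_index(np.argmax(det), det.shape)
            peak = float(det[r, c])
            r = int(np.clip(r, s // 2, render - s // 2 - 1))
            c = int(np.clip(c, s // 2, render - s // 2 - 1))
            crop = noisy[:, r - s // 2:r + s // 2, c - s // 2:c + s // 2]
        else:
            peak = np.inf
            crop = noisy
        accept = True
        if tconfig.detect_threshold is not None:
            accept &= peak > tconfig.detect_threshold
        if tconfig.photon_threshold is not None:
            accept &= float(crop.sum()) >= tconfig.photon_threshold
        if accept:
            break
    return crop


def _fill_scene_crops(images: np.ndarray, labels: np.ndarray,
                      basis: ModeBasis, tconfig: TrainingConfig,
                      optics: OpticalConfig, rng: np.random.Generator,
                      baseline) -> None:
    """Fill training crops by segmenting simulated mini blinking frames.

    Each scene simulates one frame at the acquisition emitter density under
    the sample's wavefront and passes it through the very segmentation used
    at inference, so selection effects (peak detection, isolation, photon
    threshold) and neighbour overlap are reproduced exactly.  All crops of
    one scene share that scene's label; scenes with no accepted crop are
    redrawn, falling back to an unfiltered single-emitter crop eventually.
    """
    from .blinking import AcquisitionConfig, segment_subregions, \
        simulate_frames

    n, s = images.shape[0], tconfig.subregion_size
    pupil_field = PupilFunction.flat(optics).complex_field()
    base_acq = dict(
        frame_size=tconfig.scene_size,
        mean_emitters=tconfig.emitter_density * tconfig.scene_size ** 2,
        z_range=tconfig.z_range, mean_photons=tconfig.mean_photons,
        frames_per_cycle=1, subregion_size=s,
        isolation_radius=s / 2, detect_sigma=tconfig.detect_sigma,
        photon_threshold=(tconfig.photon_threshold
                          if tconfig.photon_threshold else 1e-6),
        detect_threshold=(tconfig.detect_threshold
                          if tconfig.detect_threshold is not None else 0.0),
    )
    i = 0
    label_src = labels.copy()
    while i < n:
        label = label_src[i]
        phase = compose_wavefront(label, basis) + baseline
        crops = []
        for _ in range(max(tconfig.max_redraws, 1)):
            bg = rng.uniform(*tconfig.background_range)
            acq = AcquisitionConfig(background=bg, **base_acq)
            frame = simulate_frames(phase, 1, acq, optics, rng)[0]
            subs = segment_subregions(
                frame, np.full_like(frame.pixels, bg, dtype=float), acq)
            crops = [sub.images for sub in subs[:tconfig.max_crops_per_scene]]
            if crops:
                break
        if not crops:
            crops = [_isolated_crop(phase, replace(
                tconfig, detect_threshold=None, photon_threshold=None),
                optics, pupil_field, rng)]
        for crop in crops:
            if i >= n:
                break
            labels[i] = label
            images[i] = crop
            i += 1


# ---------------------------------------------------------------------------
# network construction and training
# ---------------------------------------------------------------------------

def build_network(input_size: int = 32, n_modes: int = 28,
                  channels: tuple[int, ...] = (8, 16, 32, 64),
                  seed: int = 0) -> ConvNet:
    """Residual CNN: strided conv downsampling, residual blocks with PReLU
    and batch norm, and a 1x1-convolution head emitting one amplitude per
    mirror mode."""
    return ConvNet(input_size=input_size, n_modes=n_modes, channels=channels,
                   in_channels=2, seed=seed)


def train_network(model: ConvNet, images: np.ndarray, labels: np.ndarray,
                  epochs: int = 12, batch_size: int = 128, lr: float = 2e-3,
                  val_fraction: float = 0.1, seed: int = 0,
                  verbose: bool = False) -> dict:
    """Mean-squared-error regression of mode amplitudes; deterministic.

    Returns a history dict with per-epoch training loss, final validation
    loss and per-mode validation RMSE.  Raises on divergence (NaN loss).
    """
    if images.shape[0] == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(seed)
    n = images.shape[0]
    n_val = max(int(n * val_fraction), 1) if n > 10 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xt, yt = images[train_idx], labels[train_idx]
    xv, yv = images[val_idx], labels[val_idx]

    opt = Adam(model, lr=lr)
    history: dict = {"train_loss": [], "lr": lr}
    n_train = xt.shape[0]
    for epoch in range(epochs):
        # step-wise decay: 1x, then 0.2x over the last third, then a short
        # 0.02x cool-down that settles the Adam equilibrium noise
        if epoch >= max(epochs - max(epochs // 10, 1), 1):
            opt.lr = lr * 0.02
        elif epoch >= 2 * epochs // 3:
            opt.lr = lr * 0.2
        else:
            opt.lr = lr
        order = rng.permutation(n_train)
        total = 0.0
        for i0 in range(0, n_train, batch_size):
            idx = order[i0:i0 + batch_size]
            pred = model.forward(xt[idx], train=True)
            diff = pred - yt[idx]
            loss = float((diff ** 2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (NaN/inf loss) at epoch {epoch}")
            model.backward((2.0 / diff.size) * diff)
            opt.step()
            total += loss * idx.size
        history["train_loss"].append(total / n_train)
        if verbose:
            print(f"epoch {epoch}: loss {history['train_loss'][-1]:.5f}")
    if n_val:
        pred = model.predict(xv)
        history["val_loss"] = float(((pred - yv) ** 2).mean())
        history["val_rmse_per_mode"] = np.sqrt(
            ((pred - yv) ** 2).mean(axis=0))
    return history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def estimate_wavefront(subregions: list[SubRegion] | np.ndarray,
                       ensemble: NetworkEnsemble,
                       network_id: int = -1) -> WavefrontEstimate:
    """Per-subregion inference with one ensemble member, aggregated.

    Returns the per-mode mean over subregions and its standard error.  The
    crops receive exactly the training-time photon normalization.  Fewer
    than two subregions raise :class:`InsufficientDetections` (the caller
    skips the mirror update).
    """
    if isinstance(subregions, np.ndarray):
        images = subregions
    else:
        images = np.stack([s.images for s in subregions]) if subregions else \
            np.zeros((0, 2, 2, 2))
    if images.shape[0] < 2:
        raise InsufficientDetections(
            f"{images.shape[0]} subregion(s); at least 2 are required")
    network_id = network_id % ensemble.n_networks
    net = ensemble.networks[network_id]
    preds = net.predict(normalize_crops(images))
    mean = preds.mean(axis=0)
    stderr = preds.std(axis=0, ddof=1) / np.sqrt(preds.shape[0])
    return WavefrontEstimate(
        mean=WavefrontCoefficients(mean, ensemble.basis_id),
        stderr=stderr.astype(float), n_subregions=preds.shape[0],
        network_id=network_id)


def characterize_response(predict, basis: ModeBasis, optics: OpticalConfig,
                          amplitude: float, n_crops: int = 25,
                          photons: float = 5_000.0, background: float = 10.0,
                          z_range: tuple[float, float] = (-600.0, 600.0),
                          rng: np.random.Generator | None = None
                          ) -> tuple[np.ndarray, dict]:
    """Response matrix of an estimator to individual mirror-mode pokes.

    For each mode the estimator runs on clean simulated crops at +amplitude
    and -amplitude; the response column is the half-difference of the two
    mean outputs divided by the amplitude (identity for an ideal estimator).

    ``predict`` is called as ``predict(images, truth)`` with normalized
    crops of shape (n, 2, S, S) and the induced coefficient vector, and must
    return (n, n_modes) estimates; passing the truth through lets an ideal
    reference estimator validate the harness arithmetic.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    k = basis.n_modes
    s = optics.psf_size
    pupil = PupilFunction.flat(optics).complex_field()
    resp = np.zeros((k, k))
    for mode in range(k):
        means = []
        for sign in (+1.0, -1.0):
            c = np.zeros(k)
            c[mode] = sign * amplitude
            phase = compose_wavefront(c, basis)
            images = np.empty((n_crops, 2, s, s), dtype=np.float32)
            for i in range(n_crops):
                xyz = np.array([[rng.uniform(-optics.pixel_size,
                                             optics.pixel_size),
                                 rng.uniform(-optics.pixel_size,
                                             optics.pixel_size),
                                 rng.uniform(*z_range)]])
                patch = _render_planes(pupil, phase, xyz, optics, s,
                                       single_precision=True)[0]
                expected = patch * (photons / 2.0) + background
                images[i] = rng.poisson(expected) - background
            preds = np.asarray(predict(normalize_crops(images), c))
            means.append(preds.mean(axis=0))
        resp[:, mode] = (means[0] - means[1]) / (2.0 * amplitude)
    off = resp - np.diag(np.diag(resp))
    summary = {
        "diagonal": np.diag(resp).copy(),
        "max_offdiag_per_column": np.abs(off).max(axis=0),
        "diagonally_dominant": bool(
            np.all(np.diag(resp) > np.abs(off).max(axis=0))),
    }
    return resp, summary


def ensemble_predictor(ensemble: NetworkEnsemble, network_id: int = 0):
    """Adapter giving a trained network the ``predict(images, truth)``
    signature used by :func:`characterize_response` (truth is ignored)."""
    net = ensemble.networks[network_id]

    def predict(images: np.ndarray, truth: np.ndarray) -> np.ndarray:
        return net.predict(images)

    return predict


# ---------------------------------------------------------------------------
# phase retrieval and mirror-mode measurement
# ---------------------------------------------------------------------------

def phase_retrieve(stack: PSFStack, optics: OpticalConfig, n_iter: int = 60,
                   background: float = 0.0) -> PupilFunction:
    """Gerchberg-Saxton pupil recovery from a through-focus intensity stack.

    Alternates between enforcing the measured amplitude in image space at
    every z (defocus applied / removed through the angular-spectrum phase)
    and the pupil support constraint.  Returns the best iterate by the
    image-space residual; warns if the residual is still decreasing-free
    (diverging) at the end.  The retrieved phase has its piston removed.
    """
    if stack.images.shape[0] < 3:
        raise ValueError("phase retrieval needs at least 3 z-slices")
    n = optics.pupil_grid
    if stack.images.shape[-1] > n:
        raise ValueError("stack images larger than the pupil grid")
    mask = optics.pupil_mask()
    amps_small = np.sqrt(np.clip(stack.images - background, 0.0, None))
    # embed measured amplitudes in the full FFT grid; pixels outside the
    # measured window are left unconstrained (the detector crop is finite)
    s = amps_small.shape[-1]
    lo = n // 2 - s // 2
    amps = np.zeros((stack.images.shape[0], n, n))
    amps[:, lo:lo + s, lo:lo + s] = amps_small
    window = np.zeros((n, n), dtype=bool)
    window[lo:lo + s, lo:lo + s] = True
    defoc = np.stack([defocus_phase(z, optics) for z in stack.z_positions])
    phasor = np.exp(1j * defoc)

    pupil = mask.astype(complex)
    best = pupil
    best_err = np.inf
    errs = []
    for _ in range(n_iter):
        pz = pupil[None] * phasor
        f = np.fft.fftshift(_fft.fft2(np.fft.ifftshift(pz, axes=(-2, -1)),
                                      axes=(-2, -1)), axes=(-2, -1))
        fa = np.abs(f)
        # match the measured amplitudes to the model's energy scale
        e_model = float((fa[:, window] ** 2).sum())
        e_meas = float((amps[:, window] ** 2).sum())
        scale = np.sqrt(e_model / max(e_meas, 1e-300))
        err = float(((fa[:, window] - scale * amps[:, window]) ** 2).sum()
                    / max(e_model, 1e-300))
        errs.append(err)
        fa_safe = np.where(fa > 0, fa, 1.0)
        f_proj = scale * amps * f / fa_safe
        f = np.where(window[None], f_proj, f)
        pz = np.fft.fftshift(_fft.ifft2(np.fft.ifftshift(f, axes=(-2, -1)),
                                        axes=(-2, -1)), axes=(-2, -1))
        pupil = (pz * np.conj(phasor)).mean(axis=0) * mask
        if err < best_err:
            best_err, best = err, pupil
    if len(errs) > 2 and errs[-1] > errs[0] and errs[-1] > 1e-9:
        warnings.warn("phase retrieval did not converge; returning the best "
                      f"iterate (residual {best_err:.3g})")
        pupil = best
    mag = np.abs(pupil) * mask
    if mag[mask].mean() > 0:
        mag = mag / mag[mask].mean()
    # the retrieved phase is defined modulo 2 pi; unwrap over the support
    wrapped = np.ma.array(np.where(mask, np.angle(pupil), 0.0), mask=~mask)
    phase = np.asarray(unwrap_phase(wrapped))
    phase = np.where(mask, phase - phase[mask].mean(), 0.0)
    return PupilFunction(magnitude=mag, phase=phase, support_mask=mask)


def measure_mirror_modes(mirror_basis: ModeBasis, optics: OpticalConfig,
                         baseline: np.ndarray | None = None,
                         photons: float = 1e6, n_iter: int = 60,
                         z_range: tuple[float, float] = (-1500.0, 1500.0),
                         z_step: float = 100.0) -> ModeBasis:
    """Measure mirror deformation modes from +-unit pokes and bead stacks.

    For every mode, bead z-stacks are rendered under +1 and -1 commanded
    units (through the mirror's coupling), both pupils are phase-retrieved,
    and the mode image is the half-difference of the two retrieved phases —
    cancelling any static baseline aberration by construction.  The
    recovered modes are returned un-orthogonalized (they are near-orthogonal
    for realistic coupling); apply ``ModeBasis.from_modes`` to re-impose
    strict orthonormality.
    """
    k = mirror_basis.n_modes
    mask = mirror_basis.mask
    base = baseline if baseline is not None else 0.0
    pupil = PupilFunction.flat(optics)
    modes = np.zeros_like(mirror_basis.modes)
    for mode in range(k):
        phases = []
        for sign in (+1.0, -1.0):
            realized = sign * mirror_basis.coupling[:, mode]
            phase = compose_wavefront(realized, mirror_basis) + base
            stack = render_bead_stack(pupil, phase, optics, z_range=z_range,
                                      z_step=z_step, photons=photons)
            pf = phase_retrieve(stack, optics, n_iter=n_iter)
            phases.append(pf.phase)
        modes[mode] = np.where(mask, (phases[0] - phases[1]) / 2.0, 0.0)
    return ModeBasis.from_modes(modes, mask, coupling=np.eye(k),
                                orthonormalize=False)

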