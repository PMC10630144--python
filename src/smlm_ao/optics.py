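"""Scalar-diffraction forward model for biplane single-molecule imaging.

Pupil-plane construction, Zernike / deformable-mirror wavefront bases,
aberration phases (defocus, refractive-index mismatch) and PSF rendering.
All lengths are nanometres, phases are radians, coordinates are row-major
with the origin at the geometric image centre (x right, y down, z positive
away from the coverslip).

The pupil is sampled on a square grid in transverse spatial frequency k
(cycles/nm); the camera image is its 2D Fourier transform, so the k-step is
1 / (pupil_grid * pixel_size) and the pupil support |k| <= NA/lambda is a
disk well inside the grid for typical configurations.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as _fft

__all__ = [
    "OpticalConfig",
    "ModeBasis",
    "WavefrontCoefficients",
    "PupilFunction",
    "EmitterState",
    "PSFStack",
    "build_zernike_basis",
    "build_mirror_basis",
    "compose_wavefront",
    "decompose_wavefront",
    "wrms",
    "defocus_phase",
    "index_mismatch_phase",
    "render_psf",
    "render_bead_stack",
    "zernike_wyant",
]


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Optical-system parameters of the biplane detection path.

    Defaults follow a 1.35-NA silicone-oil objective imaging a far-red dye
    (emission ~690 nm) onto a camera with 119 nm effective pixels, with the
    two detection planes placed symmetrically +-300 nm about nominal focus.
    """

    wavelength: float = 690.0          # emission wavelength (nm)
    na: float = 1.35                   # numerical aperture
    n_immersion: float = 1.406        # immersion-medium refractive index
    n_sample: float = 1.35            # sample-medium refractive index
    pixel_size: float = 119.0          # camera pixel pitch at sample (nm)
    pupil_grid: int = 64               # pupil samples per side (= FFT size)
    psf_size: int = 32                 # rendered image side (pixels)
    plane_offsets: tuple[float, float] = (-300.0, 300.0)  # biplane z offsets (nm)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("pupil_grid", "psf_size"):
            v = getattr(self, name)
            if v < 16 or v % 2:
                raise ValueError(f"{name} must be even and >= 16, got {v}")
        if not self.na < self.n_immersion:
            raise ValueError(
                f"NA ({self.na}) must be below the immersion index "
                f"({self.n_immersion})"
            )
        if self.na > self.n_sample:
            raise ValueError(
                f"NA ({self.na}) exceeds the sample index ({self.n_sample}): "
                "marginal rays would be evanescent in the sample medium"
            )
        # Pupil disk must fit inside the sampled k-grid.
        k_max = self.na / self.wavelength
        k_nyq = 0.5 / self.pixel_size
        if k_max >= k_nyq * (1 - 2.0 / self.pupil_grid):
            raise ValueError(
                "pupil support does not fit the k-grid; increase pupil_grid "
                "or reduce pixel_size"
            )

    # -- derived grids (computed on demand; frozen dataclass keeps no cache) --
    def k_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Centred transverse spatial-frequency coordinates (cycles/nm)."""
        n = self.pupil_grid
        dk = 1.0 / (n * self.pixel_size)
        c = (np.arange(n) - n // 2) * dk
        ky, kx = np.meshgrid(c, c, indexing="ij")
        return kx, ky

    def pupil_mask(self) -> np.ndarray:
        kx, ky = self.k_grid()
        return kx * kx + ky * ky <= (self.na / self.wavelength) ** 2

    def field_half_width(self) -> float:
        """Half-width of the rendered frame field in nm (for a psf_size crop)."""
        return 0.5 * self.psf_size * self.pixel_size


@dataclass(frozen=True)
class PupilFunction:
    """Complex pupil field: magnitude and phase on the pupil grid."""

    magnitude: np.ndarray
    phase: np.ndarray
    support_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.magnitude[~self.support_mask] != 0):
            raise ValueError("pupil magnitude must vanish outside the support")

    @classmethod
    def flat(cls, config: OpticalConfig) -> "PupilFunction":
        mask = config.pupil_mask()
        return cls(magnitude=mask.astype(float), phase=np.zeros_like(mask, float),
                   support_mask=mask)

    def complex_field(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


@dataclass
class ModeBasis:
    """Orthonormalized pupil-phase mode set (Zernike or mirror-deformation).

    Each mode has unit RMS phase over the pupil support, modes are pairwise
    orthogonal, and piston is excluded.  ``coupling`` maps commanded mode
    amplitudes to realized amplitudes in this orthonormal frame (identity
    for an ideal mirror).
    """

    modes: np.ndarray                  # (n_modes, N, N), radians
    mask: np.ndarray                   # pupil support
    coupling: np.ndarray               # (n_modes, n_modes)
    basis_id: str = ""

    def __post_init__(self) -> None:
        if self.modes.ndim != 3:
            raise ValueError("modes must be a (n_modes, N, N) array")
        if self.coupling.shape != (self.n_modes, self.n_modes):
            raise ValueError("coupling matrix shape mismatch")
        if not self.basis_id:
            h = hashlib.sha1(np.ascontiguousarray(self.modes).tobytes())
            self.basis_id = h.hexdigest()[:12]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def flat_modes(self) -> np.ndarray:
        """Modes restricted to the support, as (n_modes, n_support) rows."""
        return self.modes[:, self.mask]

    @classmethod
    def from_modes(cls, modes: np.ndarray, mask: np.ndarray,
                   coupling: np.ndarray | None = None,
                   orthonormalize: bool = True) -> "ModeBasis":
        """Build a basis from raw phase images.

        With ``orthonormalize`` the modes are mean-removed (piston excluded),
        Gram-Schmidt orthogonalized over the support and scaled to unit RMS.
        """
        modes = np.array(modes, dtype=float, copy=True)
        modes[:, ~mask] = 0.0
        if orthonormalize:
            npix = int(mask.sum())
            flat = modes[:, mask]
            out = np.zeros_like(flat)
            for k in range(flat.shape[0]):
                v = flat[k] - flat[k].mean()
                for j in range(k):
                    v -= (v @ out[j]) / npix * out[j]
                r = math.sqrt(float(v @ v) / npix)
                if r < 1e-12:
                    raise ValueError(f"mode {k} is degenerate after orthogonalization")
                out[k] = v / r
            modes = np.zeros_like(modes)
            modes[:, mask] = out
        if coupling is None:
            coupling = np.eye(modes.shape[0])
        return cls(modes=modes, mask=mask, coupling=np.asarray(coupling, float))


@dataclass(frozen=True)
class WavefrontCoefficients:
    """Amplitude vector over a mode basis (radians of W_rms per unit mode)."""

    values: np.ndarray
    basis_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficients must be finite")

    @classmethod
    def zeros(cls, basis: ModeBasis) -> "WavefrontCoefficients":
        return cls(np.zeros(basis.n_modes), basis.basis_id)

    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class EmitterState:
    """A single emitter: position relative to image centre / nominal focus."""

    x: float = 0.0          # nm, right
    y: float = 0.0          # nm, down
    z: float = 0.0          # nm, away from coverslip
    photons: float = 1000.0  # expected total detected photons (both planes)
    background: float = 0.0  # expected background photons per pixel

    def __post_init__(self) -> None:
        if self.photons < 0 or self.background < 0:
            raise ValueError("photons and background must be non-negative")


@dataclass(frozen=True)
class PSFStack:
    """Ordered stack of expected-photon images with axial coordinates."""

    images: np.ndarray        # (n_z, rows, cols)
    z_positions: np.ndarray   # (n_z,), nm

    def __post_init__(self) -> None:
        object.__setattr__(self, "images", np.asarray(self.images, float))
        object.__setattr__(self, "z_positions", np.asarray(self.z_positions, float))
        if self.images.shape[0] != self.z_positions.shape[0]:
            raise ValueError("slice count must equal the number of z positions")
        if np.any(self.images < 0):
            raise ValueError("expected photon counts must be non-negative")


# ---------------------------------------------------------------------------
# Zernike polynomials (Wyant ordering) and mode bases
# ---------------------------------------------------------------------------

_MAX_WYANT_INDEX = 120  # safely beyond the first 64 coefficients used in practice


def _wyant_nm(j: int) -> tuple[int, int, bool]:
    """Wyant single index -> (radial degree, azimuthal order, is_cosine)."""
    n = int(math.isqrt(j))
    r = j - n * n
    m = n - r // 2
    cosine = (r % 2 == 0)
    return 2 * n - m, m, cosine


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s) * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def zernike_wyant(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Zernike circle polynomial with Wyant single-index ordering.

    j=0 piston, 1/2 tilt, 3 defocus, 4/5 astigmatism, 6/7 coma, 8 spherical,
    9/10 trefoil, ...  (unnormalized; callers rescale to unit RMS).
    """
    if j < 0 or j > _MAX_WYANT_INDEX:
        raise ValueError(
            f"Wyant index {j} outside the implemented range 0..{_MAX_WYANT_INDEX}"
        )
    n, m, cosine = _wyant_nm(j)
    r = _radial_poly(n, m, rho)
    if m == 0:
        return r
    return r * (np.cos(m * theta) if cosine else np.sin(m * theta))


def build_zernike_basis(n_modes: int, config: OpticalConfig,
                        first_mode: int = 1) -> ModeBasis:
    """Wyant-ordered Zernike basis on the pupil support, unit RMS per mode.

    Piston (j=0) is always excluded; ``first_mode`` selects the first Wyant
    index included (1 = x tilt; 4 skips tilt and defocus, starting at
    astigmatism, which is the deformable-mirror-like default used in the
    reduced-scale experiments).
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if first_mode < 1:
        raise ValueError("piston (j=0) is excluded from wavefront bases")
    last = first_mode + n_modes - 1
    if last > _MAX_WYANT_INDEX:
        raise ValueError(
            f"requested Wyant index {last} exceeds the implemented limit "
            f"{_MAX_WYANT_INDEX}"
        )
    kx, ky = config.k_grid()
    mask = config.pupil_mask()
    k_max = config.na / config.wavelength
    rho = np.sqrt(kx * kx + ky * ky) / k_max
    theta = np.arctan2(ky, kx)
    modes = np.stack([zernike_wyant(j, rho, theta)
                      for j in range(first_mode, last + 1)])
    return ModeBasis.from_modes(modes, mask)


def build_mirror_basis(zernike: ModeBasis, coupling_strength: float,
                       seed: int) -> ModeBasis:
    """Synthetic "measured" deformable-mirror modes.

    Real mirror deformation shapes are cross-coupled versions of the ideal
    analytic modes.  This surrogate mixes the input Zernike modes through a
    random near-identity matrix (off-diagonal magnitudes scaled by
    ``coupling_strength``), re-orthonormalizes the mixed shapes and stores
    the resulting commanded->realized coupling matrix so a simulated mirror
    reproduces the cross-talk.
    """
    if not 0 <= coupling_strength < 0.5:
        raise ValueError("coupling_strength must lie in [0, 0.5)")
    k = zernike.n_modes
    if coupling_strength == 0:
        return ModeBasis(modes=zernike.modes.copy(), mask=zernike.mask,
                         coupling=np.eye(k))
    rng = np.random.default_rng(seed)
    mix = np.eye(k) + coupling_strength * rng.standard_normal((k, k)) * (1 - np.eye(k))
    raw = np.tensordot(mix.T, zernike.modes, axes=(1, 0))  # raw[k] = sum_j mix[j,k] Z_j
    basis = ModeBasis.from_modes(raw, zernike.mask)
    # Coupling: commanded unit of mode k realizes raw mixed shape k, expressed
    # in the orthonormalized basis (and normalized to unit RMS per command).
    npix = int(zernike.mask.sum())
    raw_flat = raw[:, zernike.mask]
    raw_flat = raw_flat - raw_flat.mean(axis=1, keepdims=True)
    raw_rms = np.sqrt((raw_flat ** 2).sum(axis=1) / npix)
    raw_flat = raw_flat / raw_rms[:, None]
    coupling = (basis.flat_modes() @ raw_flat.T) / npix  # [j, k] = <b_j, raw_k>
    basis.coupling = coupling
    return basis


# ---------------------------------------------------------------------------
# wavefront composition / decomposition / norms
# ---------------------------------------------------------------------------

def compose_wavefront(coeffs: WavefrontCoefficients | np.ndarray,
                      basis: ModeBasis) -> np.ndarray:
    """Pupil-phase image sum_k c_k * mode_k (radians, zero off support)."""
    if isinstance(coeffs, WavefrontCoefficients):
        if coeffs.basis_id != basis.basis_id:
            raise ValueError("coefficients refer to a different basis")
        values = coeffs.values
    else:
        values = np.asarray(coeffs, float)
    if values.shape != (basis.n_modes,):
        raise ValueError("coefficient length does not match the basis")
    return np.tensordot(values, basis.modes, axes=(0, 0))


def decompose_wavefront(phase: np.ndarray, basis: ModeBasis
                        ) -> tuple[WavefrontCoefficients, float]:
    """Least-squares projection onto the basis plus the residual W_rms.

    Because the basis is orthonormal over the support (RMS inner product),
    the projection is a plain inner product; the residual is the RMS of the
    unexplained, mean-removed phase.
    """
    mask = basis.mask
    npix = int(mask.sum())
    p = phase[mask]
    p = p - p.mean()  # piston is not part of any basis
    flat = basis.flat_modes()
    coeffs = flat @ p / npix
    resid = p - coeffs @ flat
    resid_rms = math.sqrt(float(resid @ resid) / npix)
    return WavefrontCoefficients(coeffs, basis.basis_id), resid_rms


def wrms(phase: np.ndarray, mask: np.ndarray) -> float:
    """Root-mean-square wavefront error over the pupil support (radians).

    The phase is taken as given: no piston or tilt removal is applied.
    """
    npix = int(np.count_nonzero(mask))
    if npix == 0:
        raise ValueError("empty pupil support")
    p = phase[mask]
    return math.sqrt(float(p @ p) / npix)


# ---------------------------------------------------------------------------
# physical aberration phases
# ---------------------------------------------------------------------------

def defocus_phase(z: float, config: OpticalConfig) -> np.ndarray:
    """Angular-spectrum defocus phase for axial displacement z (nm)."""
    if abs(z) > 5_000:
        raise ValueError("|z| above 5 um exceeds the sampling validity guard")
    kx, ky = config.k_grid()
    mask = config.pupil_mask()
    k2 = kx * kx + ky * ky
    kz2 = (config.n_immersion / config.wavelength) ** 2 - k2
    kz = np.sqrt(np.clip(kz2, 0.0, None))
    return np.where(mask, 2.0 * np.pi * z * kz, 0.0)


def index_mismatch_phase(depth: float, config: OpticalConfig) -> np.ndarray:
    """Depth-proportional aberration from sample/immersion index mismatch.

    phi(k) = 2 pi d [sqrt((n_s/lambda)^2 - k^2) - sqrt((n_i/lambda)^2 - k^2)]
    on the pupil support; evanescent regions contribute zero.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    kx, ky = config.k_grid()
    mask = config.pupil_mask()
    k2 = kx * kx + ky * ky
    kz_s = np.sqrt(np.clip((config.n_sample / config.wavelength) ** 2 - k2, 0, None))
    kz_i = np.sqrt(np.clip((config.n_immersion / config.wavelength) ** 2 - k2, 0, None))
    return np.where(mask, 2.0 * np.pi * depth * (kz_s - kz_i), 0.0)


# ---------------------------------------------------------------------------
# PSF rendering
# ---------------------------------------------------------------------------

def _render_planes(pupil_field: np.ndarray, aberration: np.ndarray,
                   emitters_xyz: np.ndarray, config: OpticalConfig,
                   out_size: int, single_precision: bool = False) -> np.ndarray:
    """Render normalized PSF patches for a batch of emitters.

    Returns (n_emitters, 2, out_size, out_size) images each summing to the
    in-support energy fraction on the *full* FFT grid (i.e. unit sum over an
    unbounded detector, before cropping).
    """
    kx, ky = config.k_grid()
    n = config.pupil_grid
    mask = config.pupil_mask()
    rows, cols = np.where(mask)
    xyz = np.atleast_2d(emitters_xyz)
    m = xyz.shape[0]
    kxm, kym = kx[mask], ky[mask]
    kzm = np.sqrt(np.clip((config.n_immersion / config.wavelength) ** 2
                          - kxm * kxm - kym * kym, 0.0, None))
    base = (pupil_field * np.exp(1j * aberration))[mask]
    out = np.empty((m, 2, out_size, out_size))
    lo = n // 2 - out_size // 2
    hi = lo + out_size
    denom = float((pupil_field * np.conj(pupil_field)).real.sum()) * n * n
    cdtype = np.complex64 if single_precision else np.complex128
    field = np.zeros((m, n, n), dtype=cdtype)
    for p, off in enumerate(config.plane_offsets):
        # phasors only on the pupil support (the rest of the grid is zero)
        phase = 2.0 * np.pi * (xyz[:, 0, None] * kxm + xyz[:, 1, None] * kym
                               + (xyz[:, 2, None] + off) * kzm)
        if single_precision:
            phase = phase.astype(np.float32)
        field[:, rows, cols] = np.exp(1j * phase) * base
        img = np.fft.fftshift(_fft.fft2(np.fft.ifftshift(field, axes=(-2, -1)),
                                        axes=(-2, -1)), axes=(-2, -1))
        intens = (img.real ** 2 + img.imag ** 2) / denom
        out[:, p] = intens[:, lo:hi, lo:hi]
    return out


def render_psf(pupil: PupilFunction, aberration: np.ndarray,
               emitter: EmitterState, config: OpticalConfig) -> np.ndarray:
    """Expected biplane photon images (2, psf_size, psf_size) for one emitter.

    Photons split equally between the two planes (50/50 beam splitter); the
    per-plane image is normalized to unit sum over an unbounded detector
    before cropping, then scaled by photons/2 and offset by the background.
    """
    half = config.field_half_width()
    if abs(emitter.x) > half or abs(emitter.y) > half:
        raise ValueError("emitter lies outside the rendered field")
    patches = _render_planes(pupil.complex_field(), aberration,
                             np.array([[emitter.x, emitter.y, emitter.z]]),
                             config, config.psf_size)[0]
    return patches * (emitter.photons / 2.0) + emitter.background


def render_bead_stack(pupil: PupilFunction, aberration: np.ndarray,
                      config: OpticalConfig,
                      z_range: tuple[float, float] = (-1500.0, 1500.0),
                      z_step: float = 100.0, photons: float = 1e6,
                      background: float = 0.0) -> PSFStack:
    """Noiseless through-focus bead stack (single detection path, no biplane).

    The default protocol covers -1.5..1.5 um in 100 nm steps (31 slices), the
    z-scan used for phase retrieval and mirror-mode measurement.
    """
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    z = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    cfg = replace(config, plane_offsets=(0.0, 0.0))
    xyz = np.zeros((z.size, 3))
    xyz[:, 2] = z
    patches = _render_planes(pupil.complex_field(), aberration, xyz, cfg,
                             config.psf_size)[:, 0]
    return PSFStack(images=patches * photons + background, z_positions=z)
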