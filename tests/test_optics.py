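"""Forward-model tests: bases, wavefront algebra, aberration phases and
PSF rendering, each checked against independent oracles where available."""

import numpy as np
import pytest
from dataclasses import replace

from smlm_ao import (EmitterState, OpticalConfig, PupilFunction,
                     WavefrontCoefficients, build_mirror_basis,
                     build_zernike_basis, compose_wavefront,
                     decompose_wavefront, defocus_phase,
                     index_mismatch_phase, ncc3d, render_bead_stack,
                     render_psf, wrms)


# ---------------------------------------------------------------------------
# configuration invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kw", [
    dict(pixel_size=-1.0),
    dict(pupil_grid=15),
    dict(psf_size=17),                   # must be even
    dict(na=1.5),                        # NA above both indices
])
def test_optical_config_rejects_invalid(kw):
    with pytest.raises(ValueError):
        OpticalConfig(**{**dict(), **kw})


def test_na_equal_sample_index_is_allowed():
    OpticalConfig(na=1.35, n_sample=1.35)  # marginal rays exactly at 90 deg


# ---------------------------------------------------------------------------
# Zernike basis (Wyant ordering)
# ---------------------------------------------------------------------------

def test_zernike_modes_unit_wrms_and_orthogonal(optics):
    basis = build_zernike_basis(10, optics)
    npix = basis.mask.sum()
    flat = basis.flat_modes()
    gram = flat @ flat.T / npix
    assert np.allclose(np.diag(gram), 1.0, atol=1e-9)
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_single_mode_basis_is_pure_tip(optics):
    basis = build_zernike_basis(1, optics)
    assert basis.n_modes == 1
    assert wrms(basis.modes[0], basis.mask) == pytest.approx(1.0, abs=1e-9)
    # tip is odd in x: antisymmetric under x -> -x on the support
    # (drop column 0, which has no mirror partner on an even-sized grid)
    m = basis.modes[0][:, 1:]
    mask = basis.mask[:, 1:]
    sym_mask = mask & mask[:, ::-1]
    assert np.allclose(m[sym_mask], -m[:, ::-1][sym_mask], atol=1e-9)


def test_zernike_mode_limit_error(optics):
    with pytest.raises(ValueError, match="limit"):
        build_zernike_basis(500, optics)


# ---------------------------------------------------------------------------
# mirror basis surrogate
# ---------------------------------------------------------------------------

def test_mirror_basis_zero_coupling_is_identity(optics, zernike6):
    mb = build_mirror_basis(zernike6, 0.0, seed=3)
    assert np.array_equal(mb.modes, zernike6.modes)
    assert np.array_equal(mb.coupling, np.eye(6))


def test_mirror_basis_deterministic(optics, zernike6):
    a = build_mirror_basis(zernike6, 0.1, seed=5)
    b = build_mirror_basis(zernike6, 0.1, seed=5)
    assert np.array_equal(a.modes, b.modes)
    assert np.array_equal(a.coupling, b.coupling)


def test_mirror_basis_modes_stay_close_to_parents(optics, zernike6):
    mb = build_mirror_basis(zernike6, 0.1, seed=5)
    npix = zernike6.mask.sum()
    for k in range(6):
        proj = (mb.modes[k][zernike6.mask]
                @ zernike6.modes[k][zernike6.mask]) / npix
        assert proj >= 0.9


# ---------------------------------------------------------------------------
# wavefront composition, decomposition, W_rms
# ---------------------------------------------------------------------------

def test_compose_zero_and_unit_coefficients(basis):
    zero = compose_wavefront(np.zeros(6), basis)
    assert wrms(zero, basis.mask) == 0.0
    one = compose_wavefront(np.eye(6)[2], basis)
    assert np.allclose(one, basis.modes[2])


def test_compose_pythagorean_norm(basis):
    c = np.zeros(6)
    c[0], c[1] = 0.3, 0.4
    phase = compose_wavefront(c, basis)
    assert wrms(phase, basis.mask) == pytest.approx(0.5, abs=1e-9)


def test_compose_rejects_basis_mismatch(basis):
    coeffs = WavefrontCoefficients(np.zeros(6), basis_id="someone-else")
    with pytest.raises(ValueError, match="different basis"):
        compose_wavefront(coeffs, basis)


def test_decompose_round_trip(basis):
    rng = np.random.default_rng(0)
    c = rng.standard_normal(6)
    coeffs, resid = decompose_wavefront(compose_wavefront(c, basis), basis)
    assert np.allclose(coeffs.values, c, atol=1e-8)
    assert resid == pytest.approx(0.0, abs=1e-8)


def test_decompose_residual_matches_pixel_oracle(optics, basis):
    rng = np.random.default_rng(1)
    phase = np.where(basis.mask, rng.standard_normal(basis.mask.shape), 0.0)
    coeffs, resid = decompose_wavefront(phase, basis)
    # independent pixel-arithmetic oracle
    p = phase[basis.mask] - phase[basis.mask].mean()
    recon = coeffs.values @ basis.flat_modes()
    oracle = np.sqrt(((p - recon) ** 2).mean())
    assert resid == pytest.approx(oracle, rel=1e-10)


def test_wrms_equals_one_line_oracle(optics, basis):
    rng = np.random.default_rng(2)
    phase = rng.standard_normal(basis.mask.shape)
    expected = float(np.sqrt(np.mean(phase[basis.mask] ** 2)))
    assert wrms(phase, basis.mask) == pytest.approx(expected, rel=1e-12)
    assert wrms(np.full_like(phase, 1.7), basis.mask) == pytest.approx(1.7)
    with pytest.raises(ValueError):
        wrms(phase, np.zeros_like(basis.mask))


def test_wrms_absolute_homogeneity(basis):
    phase = compose_wavefront(np.array([.1, -.2, .3, 0, .2, -.1]), basis)
    w = wrms(phase, basis.mask)
    assert wrms(-2.5 * phase, basis.mask) == pytest.approx(2.5 * w, rel=1e-12)


# ---------------------------------------------------------------------------
# defocus and index-mismatch phases
# ---------------------------------------------------------------------------

def test_defocus_zero_odd_and_closed_form(optics):
    assert np.all(defocus_phase(0.0, optics) == 0.0)
    z = 500.0
    plus, minus = defocus_phase(z, optics), defocus_phase(-z, optics)
    assert np.allclose(plus, -minus)
    n = optics.pupil_grid
    center = plus[n // 2, n // 2]
    expected = 2 * np.pi * z * optics.n_immersion / optics.wavelength
    assert center == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        defocus_phase(6000.0, optics)


def test_index_mismatch_zero_cases(optics):
    assert np.all(index_mismatch_phase(0.0, optics) == 0.0)
    matched = OpticalConfig(n_sample=1.406, n_immersion=1.406)
    assert np.all(index_mismatch_phase(50_000.0, matched) == 0.0)


def test_index_mismatch_is_radially_symmetric(optics, zernike6):
    """134-um depth mismatch projects onto no odd/azimuthal mode."""
    phase = index_mismatch_phase(134_000.0, optics)
    coeffs, _ = decompose_wavefront(phase, zernike6)
    azimuthal = [0, 1, 2, 3, 5]   # astigmatisms, comas, trefoil
    assert np.abs(coeffs.values[azimuthal]).max() < 1e-8
    assert abs(coeffs.values[4]) > 1.0   # spherical-family content dominates


# ---------------------------------------------------------------------------
# PSF rendering
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def flat_pupil(optics):
    return PupilFunction.flat(optics)


def test_psf_normalization_and_rotational_symmetry(optics, flat_pupil):
    img = render_psf(flat_pupil, np.zeros((64, 64)),
                     EmitterState(photons=1000.0), optics)
    assert img.sum() == pytest.approx(1000.0, rel=0.03)  # small crop loss
    # 180-degree symmetry about the centre pixel (exclude row/col 0, whose
    # partner falls outside an even-sized crop)
    core = img[:, 1:, 1:]
    assert np.allclose(core, np.rot90(core, 2, axes=(1, 2)), atol=1e-6)


def test_energy_conservation_across_planes(flat_pupil):
    """Both planes together carry the emitter's photons (within 1%) when
    the rendering window is large enough to make truncation negligible."""
    cfg = OpticalConfig(pupil_grid=128, psf_size=96)
    pupil = PupilFunction.flat(cfg)
    for z in (0.0, 500.0, 1000.0):
        img = render_psf(pupil, np.zeros((128, 128)),
                         EmitterState(z=z, photons=1000.0), cfg)
        assert img.sum() == pytest.approx(1000.0, rel=0.01)


def test_fourier_shift_theorem(optics, flat_pupil):
    """Moving the emitter one pixel translates the image one column."""
    base = render_psf(flat_pupil, np.zeros((64, 64)),
                      EmitterState(photons=1000.0), optics)
    shifted = render_psf(flat_pupil, np.zeros((64, 64)),
                         EmitterState(x=optics.pixel_size, photons=1000.0),
                         optics)
    assert np.allclose(shifted[:, :, 1:], base[:, :, :-1],
                       atol=1e-6 * base.max())


def test_piston_invisibility(optics, flat_pupil, basis):
    c = np.array([0.2, -0.1, 0.3, 0.0, 0.1, -0.2])
    aberr = compose_wavefront(c, basis)
    em = EmitterState(z=300.0, photons=1000.0)
    a = render_psf(flat_pupil, aberr, em, optics)
    b = render_psf(flat_pupil, aberr + 1.234, em, optics)
    assert np.allclose(a, b, atol=1e-9 * a.max())


def test_emitter_outside_field_rejected(optics, flat_pupil):
    with pytest.raises(ValueError, match="field"):
        render_psf(flat_pupil, np.zeros((64, 64)),
                   EmitterState(x=1e6), optics)


def test_astigmatism_rotates_between_planes(optics, flat_pupil, zernike6):
    """Vertical astigmatism elongates the defocused PSF along orthogonal
    axes on either side of focus (the biplane z-encoding)."""
    aberr = compose_wavefront(np.array([0., 1.2, 0., 0., 0., 0.]), zernike6)

    def principal_angle(img):
        h = img.shape[0]
        yy, xx = np.mgrid[0:h, 0:h] - h // 2
        w = img / img.sum()
        cov = np.array([[np.sum(w * xx * xx), np.sum(w * xx * yy)],
                        [np.sum(w * xx * yy), np.sum(w * yy * yy)]])
        vals, vecs = np.linalg.eigh(cov)
        v = vecs[:, np.argmax(vals)]
        return np.arctan2(v[1], v[0]) % np.pi

    imgs = render_psf(flat_pupil, aberr, EmitterState(photons=1e6), optics)
    ang = abs(principal_angle(imgs[0]) - principal_angle(imgs[1]))
    ang = min(ang, np.pi - ang)
    assert ang == pytest.approx(np.pi / 2, abs=0.15)


def test_direct_summation_oracle(optics):
    """FFT rendering equals an independently coded direct diffraction sum."""
    cfg = OpticalConfig(pupil_grid=16, psf_size=16, pixel_size=119.0)
    pupil = PupilFunction.flat(cfg)
    em = EmitterState(x=30.0, y=-45.0, z=200.0, photons=1.0)
    img = render_psf(pupil, np.zeros((16, 16)), em, cfg)[:, 4:12, 4:12]

    kx, ky = cfg.k_grid()
    mask = cfg.pupil_mask()
    kz = np.sqrt(np.clip((cfg.n_immersion / cfg.wavelength) ** 2
                         - kx ** 2 - ky ** 2, 0, None))
    n = cfg.pupil_grid
    coords = (np.arange(n) - n // 2) * cfg.pixel_size
    direct = np.zeros((2, 8, 8))
    for p, off in enumerate(cfg.plane_offsets):
        for iy, y in enumerate(coords[n // 2 - 4:n // 2 + 4]):
            for ix, x in enumerate(coords[n // 2 - 4:n // 2 + 4]):
                field = np.sum(mask * np.exp(
                    2j * np.pi * (kx * (em.x - x) + ky * (em.y - y)
                                  + kz * (em.z + off))))
                direct[p, iy, ix] = np.abs(field) ** 2
    direct *= (em.photons / 2.0) / (mask.sum() * n * n)
    assert np.allclose(img, direct, rtol=1e-6, atol=1e-12 * direct.max())


# ---------------------------------------------------------------------------
# bead stacks
# ---------------------------------------------------------------------------

def test_bead_stack_default_protocol(optics, flat_pupil):
    stack = render_bead_stack(flat_pupil, np.zeros((64, 64)), optics)
    assert stack.images.shape[0] == 31      # -1.5..1.5 um in 100 nm steps
    assert stack.z_positions[0] == -1500.0
    assert stack.z_positions[-1] == 1500.0
    peaks = stack.images.max(axis=(1, 2))
    assert peaks.argmax() == 15             # z = 0 is the sharpest slice


def test_bead_stack_self_similarity(optics, flat_pupil, basis):
    aberr = compose_wavefront(np.array([.2, 0, .3, 0, -.2, .1]), basis)
    a = render_bead_stack(flat_pupil, aberr, optics)
    b = render_bead_stack(flat_pupil, aberr, optics)
    assert ncc3d(a, b) == pytest.approx(1.0, abs=1e-12)
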