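"""Closed-loop control tests: Kalman fusion against closed forms and batch
oracles, network-range selection, mirror algebra, focal-shift compensation
and loop behavior with a perfect reference estimator."""

import numpy as np
import pytest

from smlm_ao import (AcquisitionConfig, KalmanState, LoopConfig, MirrorModel,
                     NetworkEnsemble, WavefrontCoefficients,
                     apply_mirror_update, build_network,
                     compensate_focal_shift, inject_dynamic_distortions,
                     kalman_update, run_closed_loop, select_network)
from smlm_ao.estimator import WavefrontEstimate


def _measurement(values, stderr, basis_id="b", n=10, network_id=0):
    return WavefrontEstimate(
        mean=WavefrontCoefficients(np.asarray(values, float), basis_id),
        stderr=np.full(len(values), stderr), n_subregions=n,
        network_id=network_id)


# ---------------------------------------------------------------------------
# Kalman filter
# ---------------------------------------------------------------------------

def test_uninformative_prior_yields_measurement():
    state = KalmanState.uninformative(3, prior_variance=1e12)
    meas = _measurement([0.5, -0.2, 0.1], stderr=0.1)
    post = kalman_update(state, meas)
    assert np.allclose(post.mean, meas.mean.values, atol=1e-9)
    assert np.allclose(post.variance, 0.1 ** 2, rtol=1e-6)


def test_two_equal_variance_measurements_average():
    state = KalmanState.uninformative(2, prior_variance=1e12)
    a = _measurement([1.0, 0.0], stderr=0.1)
    b = _measurement([0.0, 1.0], stderr=0.1)
    post = kalman_update(kalman_update(state, a), b)
    assert np.allclose(post.mean, [0.5, 0.5], atol=1e-6)
    assert np.allclose(post.variance, 0.1 ** 2 / 2, rtol=1e-6)


def test_sequence_equals_inverse_variance_batch_mean():
    """With zero process noise, k sequential updates equal the
    inverse-variance-weighted batch mean (independent closed form)."""
    rng = np.random.default_rng(0)
    values = rng.normal(0.3, 0.1, size=(6, 4))
    stderrs = rng.uniform(0.05, 0.4, size=6)
    state = KalmanState.uninformative(4, prior_variance=1e14)
    for v, s in zip(values, stderrs):
        state = kalman_update(state, _measurement(v, s))
    w = 1.0 / stderrs ** 2
    batch = (w[:, None] * values).sum(axis=0) / w.sum()
    assert np.allclose(state.mean, batch, atol=1e-10)
    assert np.allclose(state.variance, 1.0 / w.sum(), rtol=1e-6)


def test_posterior_variance_never_exceeds_either_source():
    state = KalmanState(mean=np.zeros(2), variance=np.array([0.04, 0.5]))
    meas = _measurement([0.1, 0.2], stderr=0.3)
    post = kalman_update(state, meas)
    assert np.all(post.variance <= state.variance + 1e-12)
    assert np.all(post.variance <= 0.3 ** 2 + 1e-12)


def test_measurement_floor_applied():
    state = KalmanState.uninformative(2)
    post = kalman_update(state, _measurement([1.0, 1.0], stderr=0.0))
    assert np.allclose(post.variance, state.measurement_floor, rtol=1e-6)


def test_kalman_dimension_mismatch():
    state = KalmanState.uninformative(3)
    with pytest.raises(ValueError):
        kalman_update(state, _measurement([1.0], stderr=0.1))


def test_predict_step_shifts_by_applied_delta():
    state = KalmanState(mean=np.array([1.0]), variance=np.array([1e-12]),
                        process_noise=0.0)
    post = kalman_update(state, _measurement([0.0], stderr=1e6),
                         applied_delta=np.array([-1.0]))
    assert post.mean[0] == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# network selection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_ensemble():
    nets = [build_network(32, 6, channels=(4, 8), seed=i) for i in range(3)]
    return NetworkEnsemble(nets, [(0, 0.8), (0, 1.8), (0, 3.0)], "b")


def test_large_magnitude_selects_largest_range(toy_ensemble):
    est = _measurement([2.5, 0, 0, 0, 0, 0], stderr=0.0)
    assert select_network(est, toy_ensemble) == 2


def test_small_confident_estimate_selects_smallest(toy_ensemble):
    est = _measurement([0.3, 0, 0, 0, 0, 0], stderr=0.01)
    assert select_network(est, toy_ensemble) == 0


def test_boundary_ties_resolve_to_lower_range(toy_ensemble):
    est = _measurement([0.8, 0, 0, 0, 0, 0], stderr=0.0)
    assert select_network(est, toy_ensemble) == 0
    beyond = _measurement([4.0, 0, 0, 0, 0, 0], stderr=0.0)
    assert select_network(beyond, toy_ensemble) == 2


# ---------------------------------------------------------------------------
# mirror model
# ---------------------------------------------------------------------------

def test_ideal_mirror_full_correction():
    truth = np.array([0.3, -0.4, 0.2])
    mirror = MirrorModel(commanded=np.zeros(3), coupling=np.eye(3),
                         stroke=np.inf)
    mirror = apply_mirror_update(mirror, -truth)
    assert np.allclose(truth + mirror.realized_coeffs(), 0.0, atol=1e-12)


def test_zero_delta_is_idempotent():
    mirror = MirrorModel(commanded=np.array([0.5, -0.2]),
                         coupling=np.eye(2))
    updated = apply_mirror_update(mirror, np.zeros(2))
    assert np.array_equal(updated.commanded, mirror.commanded)
    assert np.array_equal(updated.realized_coeffs(),
                          mirror.realized_coeffs())


def test_coupled_mirror_single_correction_residual():
    """One full correction leaves (I - C) @ truth for linear response."""
    rng = np.random.default_rng(1)
    coupling = np.eye(4) + 0.08 * rng.standard_normal((4, 4))
    truth = rng.standard_normal(4)
    mirror = MirrorModel(commanded=np.zeros(4), coupling=coupling,
                         stroke=np.inf)
    mirror = apply_mirror_update(mirror, -truth)
    residual = truth + mirror.realized_coeffs()
    oracle = (np.eye(4) - coupling) @ truth
    assert np.allclose(residual, oracle, atol=1e-12)


def test_stroke_limit_clips_with_warning():
    mirror = MirrorModel(commanded=np.zeros(1), coupling=np.eye(1),
                         stroke_limit=2.0)
    with pytest.warns(UserWarning, match="stroke"):
        clipped = apply_mirror_update(mirror, np.array([5.0]))
    assert clipped.commanded[0] == 2.0


def test_tanh_nonlinearity_undershoots_large_commands():
    mirror = MirrorModel(commanded=np.array([3.0]), coupling=np.eye(1),
                         stroke=4.0)
    realized = mirror.realized_coeffs()[0]
    assert realized == pytest.approx(4.0 * np.tanh(3.0 / 4.0))
    assert realized < 3.0


# ---------------------------------------------------------------------------
# focal-shift compensation
# ---------------------------------------------------------------------------

def test_focal_shift_calibration_constants():
    """-0.3 um per unit of mirror mode 5 and -0.2 um of mode 15."""
    constants = {5: -0.3, 15: -0.2}
    delta = np.zeros(28)
    delta[5] = 1.0
    assert compensate_focal_shift(delta, constants) == pytest.approx(-0.3)
    assert compensate_focal_shift(np.zeros(28), constants) == 0.0
    delta[15] = 1.0
    assert compensate_focal_shift(delta, constants) == pytest.approx(-0.5)


# ---------------------------------------------------------------------------
# closed loop with a perfect reference estimator
# ---------------------------------------------------------------------------

def _oracle_estimator(basis_id):
    def fn(subregions, true_residual):
        return WavefrontEstimate(
            mean=WavefrontCoefficients(np.array(true_residual), basis_id),
            stderr=np.full(len(true_residual), 1e-6),
            n_subregions=max(len(subregions), 2), network_id=0)
    return fn


@pytest.fixture(scope="module")
def dummy_ensemble(basis):
    net = build_network(32, 6, channels=(4, 8), seed=0)
    return NetworkEnsemble([net], [(0.0, 3.0)], basis.basis_id)


def test_oracle_loop_converges_in_one_update(basis, optics, acquisition,
                                             dummy_ensemble):
    truth = np.array([0.5, -0.3, 0.4, 0.0, 0.2, -0.1])
    mirror = MirrorModel(commanded=np.zeros(6), coupling=np.eye(6),
                         stroke=np.inf)
    loop = LoopConfig(max_updates=5)
    rng = np.random.default_rng(3)
    trace = run_closed_loop(truth, dummy_ensemble, mirror, basis, optics,
                            acquisition, loop, rng,
                            estimator_fn=_oracle_estimator(basis.basis_id))
    residuals = trace.residuals()
    assert residuals[0] == pytest.approx(np.linalg.norm(truth))
    assert residuals[1] < 1e-6


def test_loop_trace_is_bitwise_deterministic(basis, optics, acquisition,
                                             dummy_ensemble):
    truth = np.array([0.4, 0.0, -0.2, 0.1, 0.0, 0.3])
    frames = []
    for _ in range(2):
        mirror = MirrorModel(commanded=np.zeros(6), coupling=basis.coupling)
        rng = np.random.default_rng(11)
        trace = run_closed_loop(
            truth, dummy_ensemble, mirror, basis, optics, acquisition,
            LoopConfig(max_updates=3), rng,
            estimator_fn=_oracle_estimator(basis.basis_id))
        frames.append(trace.to_dataframe())
    assert frames[0].equals(frames[1])


def test_dynamic_injections_have_exact_level_and_marking(
        basis, optics, acquisition, dummy_ensemble):
    mirror = MirrorModel(commanded=np.zeros(6), coupling=np.eye(6),
                         stroke=np.inf)
    rng = np.random.default_rng(5)
    trace = inject_dynamic_distortions(
        dummy_ensemble, mirror, basis, optics, acquisition,
        LoopConfig(max_updates=6), schedule=[1, 4], level=0.75, rng=rng,
        estimator_fn=_oracle_estimator(basis.basis_id))
    rows = trace.rows
    injected = [r["update"] for r in rows if r.get("injected")]
    assert injected == [1, 4]
    # the injected distortion W_rms is exactly 0.75 by construction: the
    # pre-injection residual was ~0 (oracle loop), so the jump equals it
    assert rows[3]["residual_wrms"] < 1e-4          # recovered before cycle 4
    # after the second injection the filter needs a couple of cycles to
    # re-converge (its posterior was confident before the jump)
    assert rows[-1]["residual_wrms"] < 0.01


def test_loop_rejects_mismatched_truth_length(basis, optics, acquisition,
                                              dummy_ensemble):
    mirror = MirrorModel(commanded=np.zeros(6), coupling=np.eye(6))
    with pytest.raises(ValueError):
        run_closed_loop(np.zeros(5), dummy_ensemble, mirror, basis, optics,
                        acquisition, LoopConfig(), np.random.default_rng(0))


def test_loop_config_validation():
    with pytest.raises(ValueError):
        LoopConfig(gain=1.5)
    with pytest.raises(ValueError):
        LoopConfig(max_updates=0)
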