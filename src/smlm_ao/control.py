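"""Closed-loop mirror control driven by learned wavefront estimates.

Per-mode scalar Kalman filters fuse the network measurements taken before
and after each correction; the posterior drives the next deformable-mirror
update through a simulated mirror with cross-coupling, a tanh stroke
nonlinearity and optional actuation noise.  Radially symmetric mirror modes
shift the apparent focal plane; the loop compensates with a simulated stage
move using empirically calibrated constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blinking import (AcquisitionConfig, segment_subregions, simulate_frames,
                       temporal_median_background)
from .estimator import (InsufficientDetections, NetworkEnsemble,
                        WavefrontEstimate, estimate_wavefront)
from .optics import (ModeBasis, OpticalConfig, WavefrontCoefficients,
                     compose_wavefront)

__all__ = [
    "MirrorModel",
    "KalmanState",
    "LoopConfig",
    "LoopTrace",
    "kalman_update",
    "select_network",
    "apply_mirror_update",
    "compensate_focal_shift",
    "run_closed_loop",
    "inject_dynamic_distortions",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MirrorModel:
    """Simulated deformable mirror.

    The realized wavefront (in orthonormal mode coordinates) is
    ``coupling @ (stroke * tanh(response_gain * commanded / stroke))`` plus
    seeded per-update actuation noise; ``stroke=inf`` gives a linear mirror.
    """

    commanded: np.ndarray                    # per-mode commanded amplitudes
    coupling: np.ndarray                     # realized = coupling @ f(commanded)
    response_gain: float = 1.0
    stroke: float = 4.0                      # rad/mode; saturation scale
    stroke_limit: float = 6.0                # hard clip on commanded amplitude
    actuation_noise: float = 0.0             # W_rms scale of per-update noise
    noise: np.ndarray | None = None          # frozen noise of the last update

    @classmethod
    def ideal(cls, n_modes: int, **kw) -> "MirrorModel":
        return cls(commanded=np.zeros(n_modes), coupling=np.eye(n_modes), **kw)

    def realized_coeffs(self) -> np.ndarray:
        c = self.response_gain * self.commanded
        if np.isfinite(self.stroke):
            c = self.stroke * np.tanh(c / self.stroke)
        out = self.coupling @ c
        if self.noise is not None:
            out = out + self.noise
        return out


@dataclass(frozen=True)
class KalmanState:
    """Independent per-mode scalar posteriors of the residual distortion."""

    mean: np.ndarray                         # radians per mode
    variance: np.ndarray                     # radians^2 per mode
    process_noise: float = 0.05 ** 2         # variance inflation per update
    measurement_floor: float = 0.02 ** 2     # minimum measurement variance

    def __post_init__(self) -> None:
        if np.any(self.variance <= 0):
            raise ValueError("posterior variance must stay positive")

    @classmethod
    def uninformative(cls, n_modes: int, prior_variance: float = 1e6,
                      **kw) -> "KalmanState":
        return cls(mean=np.zeros(n_modes),
                   variance=np.full(n_modes, prior_variance), **kw)


@dataclass(frozen=True)
class LoopConfig:
    """Closed-loop schedule and stop rule."""

    max_updates: int = 20
    frames_per_cycle: int = 50
    frames_chunk: int = 10                   # frames acquired per burst
    gain: float = 1.0                        # fraction of posterior applied
    stop_threshold: float = 0.1              # posterior W_rms to declare done
    stop_consecutive: int = 2                # cycles below threshold to stop
    max_subregions: int = 40                 # inference budget per cycle
    # stage compensation, um of focus per unit commanded amplitude, keyed by
    # mode index (radially symmetric modes only)
    focal_shift_constants: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.gain <= 1:
            raise ValueError("gain must lie in (0, 1]")
        if self.max_updates < 1:
            raise ValueError("max_updates must be >= 1")


@dataclass
class LoopTrace:
    """Per-update record of one closed-loop run (row 0 is the pre-loop state)."""

    rows: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.rows.append(kw)

    def __len__(self) -> int:
        return len(self.rows)

    def residuals(self) -> np.ndarray:
        """True residual W_rms per update, the last value carried forward
        for runs that stopped early."""
        return np.array([r["residual_wrms"] for r in self.rows])

    def to_dataframe(self) -> pd.DataFrame:
        vectors = ("commanded", "estimate_mean", "estimate_stderr")
        recs = []
        for r in self.rows:
            rec = {k: v for k, v in r.items() if k not in vectors}
            for key in vectors:
                if isinstance(r.get(key), np.ndarray):
                    for i, v in enumerate(r[key]):
                        rec[f"{key}_{i}"] = v
            recs.append(rec)
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def kalman_update(state: KalmanState, measurement: WavefrontEstimate,
                  applied_delta: np.ndarray | None = None) -> KalmanState:
    """One predict/update step of the per-mode scalar Kalman filters.

    Predict: the mean shifts by the mirror delta applied since the last
    measurement and the variance inflates by the process noise.  Update:
    standard scalar fusion with measurement variance ``stderr**2`` floored
    at the configured minimum.
    """
    mean = state.mean.astype(float).copy()
    var = state.variance.astype(float).copy()
    if measurement.mean.values.shape != mean.shape:
        raise ValueError("measurement dimension does not match the filter")
    if applied_delta is not None:
        if np.asarray(applied_delta).shape != mean.shape:
            raise ValueError("applied delta dimension mismatch")
        mean = mean + np.asarray(applied_delta, float)
        var = var + state.process_noise
    r = np.maximum(np.asarray(measurement.stderr, float) ** 2,
                   state.measurement_floor)
    if not np.all(np.isfinite(r)):
        raise ValueError("measurement standard errors must be finite")
    gain = var / (var + r)
    mean = mean + gain * (measurement.mean.values - mean)
    var = var * r / (var + r)   # stable form of (1 - gain) * var
    return replace(state, mean=mean, variance=var)


def select_network(estimate: WavefrontEstimate,
                   ensemble: NetworkEnsemble) -> int:
    """Range selection from the estimate magnitude and its uncertainty.

    The smallest-range network whose upper bound contains
    ``magnitude + 2 * uncertainty`` is chosen (boundary inclusive, so ties
    fall to the lower range); if none contains it, the largest-range
    network is used.
    """
    m = estimate.magnitude() + 2.0 * estimate.uncertainty()
    for i, (_, upper) in enumerate(ensemble.ranges):
        if m <= upper:
            return i
    return ensemble.n_networks - 1


def apply_mirror_update(mirror: MirrorModel, delta: np.ndarray,
                        rng: np.random.Generator | None = None
                        ) -> MirrorModel:
    """Add ``delta`` to the commanded mirror state.

    Commanded amplitudes beyond the stroke limit are clipped with a warning;
    with nonzero actuation noise a fresh seeded perturbation is drawn.
    """
    delta = np.asarray(delta, float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("mirror delta must be finite")
    commanded = mirror.commanded + delta
    if np.any(np.abs(commanded) > mirror.stroke_limit):
        warnings.warn("commanded mirror amplitude beyond the stroke limit; "
                      "clipping")
        commanded = np.clip(commanded, -mirror.stroke_limit,
                            mirror.stroke_limit)
    noise = mirror.noise
    if mirror.actuation_noise > 0 and np.any(delta != 0):
        if rng is None:
            raise ValueError("actuation noise requires a seeded generator")
        raw = rng.standard_normal(commanded.size)
        noise = raw / max(np.linalg.norm(raw), 1e-12) * mirror.actuation_noise
    return replace(mirror, commanded=commanded, noise=noise)


def compensate_focal_shift(delta: np.ndarray | WavefrontCoefficients,
                           constants: dict[int, float]) -> float:
    """Stage focus offset (um) compensating mirror-induced focal shift.

    ``offset = sum_k constants[k] * delta_k`` over the calibrated radially
    symmetric modes (e.g. -0.3 um and -0.2 um per unit amplitude for the
    two spherical-family modes of a 28-mode mirror).
    """
    values = (delta.values if isinstance(delta, WavefrontCoefficients)
              else np.asarray(delta, float))
    return float(sum(c * values[k] for k, c in constants.items()
                     if k < values.size))


# ---------------------------------------------------------------------------
# the closed loop
# ---------------------------------------------------------------------------

def run_closed_loop(true_distortion: np.ndarray | WavefrontCoefficients,
                    ensemble: NetworkEnsemble, mirror: MirrorModel,
                    basis: ModeBasis, optics: OpticalConfig,
                    acquisition: AcquisitionConfig, loop: LoopConfig,
                    rng: np.random.Generator,
                    estimator_fn=None,
                    injection_schedule: dict[int, float] | None = None
                    ) -> LoopTrace:
    """Run the full sense-infer-correct loop in simulation.

    Every cycle simulates ``frames_per_cycle`` blinking frames under the
    current residual wavefront (truth + realized mirror), median-subtracts
    the background, segments subregions, infers mode amplitudes with the
    currently selected network, fuses the measurement into the Kalman
    posterior and commands ``-gain * posterior`` to the mirror.  Cycles with
    fewer than two usable subregions skip the mirror update.  The returned
    trace records the simulation-truth residual W_rms after every cycle.

    ``estimator_fn(subregions, true_residual) -> WavefrontEstimate`` can
    replace the network inference (reference/oracle experiments).
    ``injection_schedule`` maps cycle index -> W_rms of a random distortion
    added to the truth at the start of that cycle.
    """
    truth = np.array(true_distortion.values if isinstance(
        true_distortion, WavefrontCoefficients) else true_distortion,
        dtype=float)
    k = basis.n_modes
    if truth.shape != (k,):
        raise ValueError("true distortion length does not match the basis")
    state = KalmanState.uninformative(k)
    trace = LoopTrace()
    current_net = ensemble.n_networks - 1
    focal_offset_um = 0.0
    last_delta: np.ndarray | None = None
    below = 0

    def residual_wrms(mir: MirrorModel) -> float:
        return float(np.linalg.norm(truth + mir.realized_coeffs()))

    trace.append(update=0, commanded=mirror.commanded.copy(),
                 estimate_mean=None, estimate_stderr=None,
                 network_id=current_net, n_subregions=0,
                 residual_wrms=residual_wrms(mirror),
                 focal_shift_um=focal_offset_um, injected=False,
                 skipped=False)

    for cycle in range(1, loop.max_updates + 1):
        injected = False
        if injection_schedule and cycle in injection_schedule:
            level = injection_schedule[cycle]
            raw = rng.standard_normal(k)
            truth += raw / max(np.linalg.norm(raw), 1e-12) * level
            injected = True
        residual = truth + mirror.realized_coeffs()
        phase = compose_wavefront(residual, basis)
        # acquire in bursts and stop early once the inference budget is met
        # (well-corrected wavefronts yield many detections per frame)
        subregions = []
        acquired = 0
        while acquired < loop.frames_per_cycle:
            n_burst = min(loop.frames_chunk,
                          loop.frames_per_cycle - acquired)
            frames = simulate_frames(phase, n_burst, acquisition, optics,
                                     rng, z_offset=-1000.0 * focal_offset_um)
            acquired += n_burst
            window = n_burst if n_burst % 2 else n_burst - 1
            background = temporal_median_background(frames, window)
            for f in frames:
                subregions.extend(
                    segment_subregions(f, background, acquisition))
            if len(subregions) >= loop.max_subregions:
                break
        subregions = subregions[:loop.max_subregions]
        try:
            if estimator_fn is not None:
                est = estimator_fn(subregions, residual)
            else:
                est = estimate_wavefront(subregions, ensemble, current_net)
                # dynamic switching: if the estimate falls in a different
                # network's range, re-infer the same subregions with it; a
                # smaller-range network whose own estimate contradicts its
                # range (saturation) is rejected and the original kept
                selected = select_network(est, ensemble)
                if selected != current_net:
                    est2 = estimate_wavefront(subregions, ensemble, selected)
                    upper = ensemble.ranges[selected][1]
                    if (selected > current_net
                            or est2.magnitude() + 2 * est2.uncertainty()
                            <= upper):
                        current_net, est = selected, est2
        except InsufficientDetections:
            trace.append(update=cycle, commanded=mirror.commanded.copy(),
                         estimate_mean=None, estimate_stderr=None,
                         network_id=current_net,
                         n_subregions=len(subregions),
                         residual_wrms=residual_wrms(mirror),
                         focal_shift_um=focal_offset_um, injected=injected,
                         skipped=True)
            last_delta = None
            continue
        state = kalman_update(state, est, applied_delta=last_delta)
        posterior_wrms = float(np.linalg.norm(state.mean))
        delta = -loop.gain * state.mean
        mirror = apply_mirror_update(mirror, delta, rng)
        focal_offset_um += compensate_focal_shift(
            delta, loop.focal_shift_constants)
        last_delta = delta
        current_net = select_network(est, ensemble)
        trace.append(update=cycle, commanded=mirror.commanded.copy(),
                     estimate_mean=est.mean.values.copy(),
                     estimate_stderr=np.asarray(est.stderr).copy(),
                     network_id=est.network_id,
                     n_subregions=est.n_subregions,
                     residual_wrms=residual_wrms(mirror),
                     focal_shift_um=focal_offset_um, injected=injected,
                     skipped=False)
        below = below + 1 if posterior_wrms < loop.stop_threshold else 0
        if injection_schedule is None and below >= loop.stop_consecutive:
            break
    return trace


def inject_dynamic_distortions(ensemble: NetworkEnsemble, mirror: MirrorModel,
                               basis: ModeBasis, optics: OpticalConfig,
                               acquisition: AcquisitionConfig,
                               loop: LoopConfig,
                               schedule: dict[int, float] | list[int],
                               level: float, rng: np.random.Generator,
                               estimator_fn=None) -> LoopTrace:
    """Closed loop under sudden random wavefront changes.

    At every scheduled cycle a random distortion of exactly the target
    W_rms (e.g. 0.75 rad) is added to the truth; the loop keeps running
    autonomously and the trace marks the injection cycles.
    """
    if not isinstance(schedule, dict):
        schedule = {int(c): float(level) for c in schedule}
    else:
        schedule = {int(c): float(v) for c, v in schedule.items()}
    return run_closed_loop(np.zeros(basis.n_modes), ensemble, mirror, basis,
                           optics, acquisition, loop, rng,
                           estimator_fn=estimator_fn,
                           injection_schedule=schedule)
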