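"""Validated run configuration (YAML) binding all pipeline sections together.

Every section is validated against the corresponding module's invariants at
load time and unknown keys are rejected, so a typo fails fast with a
field-level message instead of silently running a wrong experiment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .blinking import AcquisitionConfig
from .control import LoopConfig
from .estimator import TrainingConfig
from .metric_ao import MetricAOConfig
from .optics import ModeBasis, OpticalConfig, build_mirror_basis, \
    build_zernike_basis

__all__ = ["RunConfig", "load_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsSection(_Section):
    wavelength: float = 690.0
    na: float = 1.35
    n_immersion: float = 1.406
    n_sample: float = 1.35
    pixel_size: float = 119.0
    pupil_grid: int = 64
    psf_size: int = 32
    plane_offsets: tuple[float, float] = (-300.0, 300.0)

    def build(self) -> OpticalConfig:
        return OpticalConfig(**self.model_dump())


class BasisSection(_Section):
    n_modes: int = 6
    first_mode: int = 4          # Wyant index of the first included mode
    coupling_strength: float = 0.1
    seed: int = 7

    def build(self, optics: OpticalConfig) -> ModeBasis:
        zern = build_zernike_basis(self.n_modes, optics,
                                   first_mode=self.first_mode)
        return build_mirror_basis(zern, self.coupling_strength, self.seed)


class AcquisitionSection(_Section):
    frame_size: int = 128
    mean_emitters: float = 13.0
    z_range: tuple[float, float] = (-1000.0, 1000.0)
    mean_photons: float = 2500.0
    background: float = 10.0
    frames_per_cycle: int = 20
    photon_threshold: float = 1500.0
    subregion_size: int = 32
    isolation_radius: float = 16.0
    detect_sigma: float = 1.0
    detect_threshold: float = 12.0

    def build(self) -> AcquisitionConfig:
        return AcquisitionConfig(**self.model_dump())


class NetworkSection(_Section):
    amplitude_range: tuple[float, float]
    n_samples: int = 8000
    epochs: int = 20
    # optional extra samples concentrated in the upper part of the range,
    # where the network actually operates before handing off downward
    reinforce_range: tuple[float, float] | None = None
    reinforce_samples: int = 0
    batch_size: int = 256
    lr: float = 3e-3
    channels: tuple[int, ...] = (8, 16, 32, 64)


class TrainingSection(_Section):
    networks: list[NetworkSection] = Field(
        default_factory=lambda: [
            NetworkSection(amplitude_range=(0.0, 0.8), n_samples=13000,
                           epochs=24),
            NetworkSection(amplitude_range=(0.0, 1.8), n_samples=8000,
                           epochs=16, lr=2e-3, reinforce_range=(0.9, 1.8),
                           reinforce_samples=6000),
            NetworkSection(amplitude_range=(0.0, 3.0), n_samples=6000,
                           epochs=16, lr=2e-3, reinforce_range=(1.5, 3.0),
                           reinforce_samples=5000),
        ])
    # each wider-range network starts from the previous network's weights
    # (curriculum transfer); cold-started networks need more epochs
    warm_start: bool = True
    photon_range: tuple[float, float] = (1000.0, 8000.0)
    background_range: tuple[float, float] = (2.0, 20.0)
    z_range: tuple[float, float] = (-1000.0, 1000.0)
    subregion_size: int = 32
    seed: int = 0

    @field_validator("networks")
    @classmethod
    def _ranges_increase(cls, nets):
        uppers = [n.amplitude_range[1] for n in nets]
        if any(b <= a for a, b in zip(uppers, uppers[1:])):
            raise ValueError("network amplitude ranges must increase")
        return nets

    def build(self, index: int, part: int = 0) -> TrainingConfig:
        net = self.networks[index]
        if part == 0:
            amp, n = net.amplitude_range, net.n_samples
        else:
            amp, n = net.reinforce_range, net.reinforce_samples
        return TrainingConfig(
            n_samples=n,
            amplitude_range=amp,
            photon_range=self.photon_range,
            background_range=self.background_range,
            z_range=self.z_range,
            subregion_size=self.subregion_size,
            seed=self.seed + 10 * index + part,
        )

    def build_parts(self, index: int) -> list[TrainingConfig]:
        net = self.networks[index]
        parts = [self.build(index, 0)]
        if net.reinforce_range is not None and net.reinforce_samples > 0:
            parts.append(self.build(index, 1))
        return parts


class LoopSection(_Section):
    max_updates: int = 20
    frames_per_cycle: int = 50
    frames_chunk: int = 10
    gain: float = 1.0
    stop_threshold: float = 0.1
    stop_consecutive: int = 2
    max_subregions: int = 40
    focal_shift_constants: dict[int, float] = Field(default_factory=dict)
    mirror_stroke: float = 4.0
    mirror_response_gain: float = 1.0
    mirror_actuation_noise: float = 0.0

    def build(self) -> LoopConfig:
        return LoopConfig(
            max_updates=self.max_updates,
            frames_per_cycle=self.frames_per_cycle,
            frames_chunk=self.frames_chunk, gain=self.gain,
            stop_threshold=self.stop_threshold,
            stop_consecutive=self.stop_consecutive,
            max_subregions=self.max_subregions,
            focal_shift_constants=dict(self.focal_shift_constants))


class MetricAOSection(_Section):
    n_amplitudes: int = 11
    amplitude_span: tuple[float, float] = (-1.0, 1.0)
    n_iterations: int = 5
    mask_sigma: float = 2.0
    fit_window: int | None = 5

    def build(self) -> MetricAOConfig:
        return MetricAOConfig(**self.model_dump())


class RunConfig(_Section):
    seed: int = 1
    output_dir: str = "runs/out"
    optics: OpticsSection = Field(default_factory=OpticsSection)
    basis: BasisSection = Field(default_factory=BasisSection)
    acquisition: AcquisitionSection = Field(default_factory=AcquisitionSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    loop: LoopSection = Field(default_factory=LoopSection)
    metric_ao: MetricAOSection = Field(default_factory=MetricAOSection)

    def config_hash(self) -> str:
        import hashlib
        blob = repr(sorted(self.model_dump().items())).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults if no path)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def train_ensemble(run_cfg: RunConfig, basis: ModeBasis,
                   optics: OpticalConfig, verbose: bool = False):
    """Train the configured small/medium/large network ensemble.

    The canonical entry point used by the CLI, the test suite and the
    reproduction script, so every consumer trains under the identical
    protocol.  Returns (ensemble, histories).
    """
    from .estimator import (NetworkEnsemble, build_network,
                            generate_training_set, train_network)

    nets, ranges, histories = [], [], []
    for i, section in enumerate(run_cfg.training.networks):
        xs, ys = [], []
        for tc in run_cfg.training.build_parts(i):
            x, y = generate_training_set(basis, tc, optics)
            xs.append(x)
            ys.append(y)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        net = build_network(input_size=run_cfg.training.subregion_size,
                            n_modes=basis.n_modes,
                            channels=section.channels,
                            seed=run_cfg.seed + i)
        if (run_cfg.training.warm_start and nets
                and nets[-1].arch["channels"] == net.arch["channels"]):
            net.load_state_arrays(nets[-1].state_arrays())
        hist = train_network(net, x, y, epochs=section.epochs,
                             batch_size=section.batch_size, lr=section.lr,
                             seed=run_cfg.seed + 100 + i, verbose=verbose)
        net.metadata = {"amplitude_range": list(section.amplitude_range),
                        "normalization": "per-crop total-photon division",
                        "basis_id": basis.basis_id}
        nets.append(net)
        ranges.append(tuple(section.amplitude_range))
        histories.append(hist)
    return NetworkEnsemble(networks=nets, ranges=ranges,
                           basis_id=basis.basis_id), histories
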