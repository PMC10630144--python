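"""Shared fixtures: optical configuration, the reduced-scale mirror basis,
and the trained network ensemble (session-scoped; training runs once)."""

from __future__ import annotations

import numpy as np
import pytest

from smlm_ao import (AcquisitionConfig, LoopConfig, MirrorModel,
                     OpticalConfig, build_mirror_basis, build_zernike_basis,
                     run_closed_loop)
from smlm_ao.config import RunConfig, train_ensemble


@pytest.fixture(scope="session")
def optics():
    return OpticalConfig()


@pytest.fixture(scope="session")
def zernike6(optics):
    """Six analytic modes: astigmatisms, comas, spherical, trefoil."""
    return build_zernike_basis(6, optics, first_mode=4)


@pytest.fixture(scope="session")
def basis(optics, zernike6):
    """The reduced-scale mirror basis with 10% seeded cross-coupling."""
    return build_mirror_basis(zernike6, 0.1, 7)


@pytest.fixture(scope="session")
def acquisition():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def ensemble(run_cfg, basis, optics):
    """The trained small/medium/large ensemble (the expensive fixture)."""
    ens, _ = train_ensemble(run_cfg, basis, optics)
    return ens


@pytest.fixture(scope="session")
def fig2e_traces(ensemble, basis, optics, acquisition):
    """Closed-loop compensation runs: 11 induced levels x 15 repeats."""
    loop = LoopConfig()
    levels = 0.25 * np.arange(1, 12)
    traces = {float(lv): [] for lv in levels}
    for il, lv in enumerate(levels):
        for rep in range(15):
            rng = np.random.default_rng([101, il, rep])
            raw = rng.standard_normal(basis.n_modes)
            c = raw / np.linalg.norm(raw) * lv
            mirror = MirrorModel(commanded=np.zeros(basis.n_modes),
                                 coupling=basis.coupling)
            traces[float(lv)].append(
                run_closed_loop(c, ensemble, mirror, basis, optics,
                                acquisition, loop, rng))
    return traces
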