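# smlm-ao

A fully simulated, testable closed-loop implementation of learning-driven
adaptive optics for single-molecule localization microscopy (SMLM).

Imaging single molecules deep inside tissue distorts their emission
patterns (PSFs): refractive-index inhomogeneities add a wavefront error
shared by every molecule in the field, destroying the axial shape
modulation that 3D SMLM depends on. Classic sensorless adaptive optics
corrects this by trial-and-error — poke the deformable mirror, score an
image-quality metric, repeat — which is slow and unstable on volumetric
blinking data. The approach simulated here instead *infers* the shared
wavefront directly from the blinking molecules themselves: a convolutional
network maps each detected emission pattern to a vector of mirror-mode
amplitudes, a Kalman filter fuses the estimates taken before and after
each correction, and the mirror is updated in closed loop — typically a
handful of updates for full compensation.

The package contains every piece of that loop as importable, tested
components:

| module | contents |
|---|---|
| `smlm_ao.optics` | scalar-diffraction biplane PSF model, Zernike (Wyant) and synthetic mirror-mode bases, defocus / index-mismatch phases, bead z-stacks |
| `smlm_ao.blinking` | blinking-frame synthesis (Poisson emitters, exponential photons, Poisson noise), temporal-median background, subregion segmentation |
| `smlm_ao.estimator` | training-set synthesis, the residual-CNN regressor (pure-numpy engine in `smlm_ao.nn`), the three-range network ensemble, Gerchberg–Saxton phase retrieval, mirror-mode measurement |
| `smlm_ao.control` | per-mode Kalman filters, network switching, the simulated mirror (coupling + stroke nonlinearity), focal-shift compensation, the closed loop |
| `smlm_ao.metric_ao` | metric-based AO baseline: radial-symmetry centring, Gaussian-masked peak metric, quadratic sweeps |
| `smlm_ao.evaluation` | 3D NCC, Poisson Fisher information / CRLB, convergence statistics |
| `smlm_ao.config` / `smlm_ao.cli` | validated YAML run configs and the `smlm-ao` command line |

## The model in brief

A pupil function `P(k) = A(k)·e^{iφ(k)}` on `|k| ≤ NA/λ` renders each
emitter via `|FT{P·e^{i(tilt+defocus+aberration)}}|²` into two detection
planes offset ±300 nm. Wavefronts live in an orthonormal mirror-mode basis
(unit coefficient = 1 rad W_rms), so the coefficient norm is the total
wavefront error. The network estimates the coefficient vector `c` from a
background-subtracted biplane crop; per-mode scalar Kalman filters with
measurement variance `stderr²` drive mirror updates `Δ = −posterior`.
`docs/methods.md` has the full account, defaults, and limitations.

## Worked example

```python
import numpy as np
from smlm_ao import (MirrorModel, run_closed_loop)
from smlm_ao.config import RunConfig, train_ensemble

cfg = RunConfig(seed=1)
optics = cfg.optics.build()
basis = cfg.basis.build(optics)          # 6 coupled mirror modes
ens, _ = train_ensemble(cfg, basis, optics)   # trains 3 CNNs (~12 min)

rng = np.random.default_rng(7)
direction = rng.standard_normal(6)
induced = direction / np.linalg.norm(direction) * 1.5   # 1.5 rad W_rms
mirror = MirrorModel(commanded=np.zeros(6), coupling=basis.coupling)
trace = run_closed_loop(induced, ens, mirror, basis, optics,
                        cfg.acquisition.build(), cfg.loop.build(), rng)
print(np.round(trace.residuals(), 3))
```

prints the true residual wavefront error (rad W_rms) before the loop and
after each mirror update:

```
[1.5   0.837 0.397 0.143 0.071 0.04 ]
```

— the 1.5 rad distortion roughly halves at the first update and settles
near the noise floor (&lt;0.1 rad) within five updates, after which the
posterior-based stop rule ends the loop.

The same experiment from the shell:

```
smlm-ao train --seed 1                     # writes runs/out/ensemble/
smlm-ao run-loop --ensemble runs/out/ensemble --levels 11 --repeats 15
smlm-ao evaluate --traces runs/out
```

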