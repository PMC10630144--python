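# Methods

This package simulates, end to end, a learning-driven adaptive-optics (AO)
loop for single-molecule localization microscopy (SMLM): single-molecule
blinking frames are synthesized under a shared wavefront distortion, a
convolutional network infers the distortion from segmented emission
patterns, a Kalman filter fuses the inferences across correction cycles,
and a simulated deformable mirror applies the compensation. A metric-based
AO baseline and quantitative evaluation tools (3D normalized
cross-correlation, Poisson Fisher information / CRLB) complete the loop.

## Optical model

The image of a point emitter is computed by scalar diffraction: the pupil
field `P(k) = A(k) exp(i φ(k))` on the disk `|k| ≤ NA/λ` is Fourier
transformed and squared. Emitter position enters as a tilt
(`2π(k_x x + k_y y)`) and angular-spectrum defocus
(`2π z √((n_i/λ)² − |k|²)`); refractive-index mismatch between sample
(n = 1.35) and immersion oil (n = 1.406) contributes a depth-proportional,
radially symmetric phase. Detection is biplane: a 50/50 split onto two
planes offset ±300 nm axially (the separation is configurable; the
published system does not state its value). Photons split equally between
planes; each plane's diffraction pattern is normalized to unit sum over an
unbounded detector before cropping, so photon counts are conserved up to
crop truncation (≤ ~3 % on the default 32-pixel crop, < 1 % for a 96-pixel
window). The camera model is Poisson-only — sCMOS read-noise maps,
vectorial/polarization effects and dipole orientation are out of scope.

Default optics: λ = 690 nm (a far-red dye inside a 731/137 band-pass),
NA = 1.35 silicone-oil objective, 119 nm pixels, 64-point pupil grid.
Wavefronts are represented on a mode basis with unit-RMS normalization:
one coefficient unit equals 1 rad of W_rms for that mode, so the Euclidean
norm of a coefficient vector is the total W_rms of the composed wavefront.
W_rms is always the plain RMS of the pupil phase over the support — no
piston/tilt removal (piston is excluded from every basis; tilt is included
in the norm whenever tilt modes are part of the basis).

## Mode bases and the mirror surrogate

Zernike circle polynomials in Wyant ordering are sampled on the pupil
support, mean-removed, Gram–Schmidt orthogonalized and scaled to unit RMS.
Real deformable-mirror deformation shapes are cross-coupled versions of
ideal modes; since measured mirror shapes are instrument-specific, the
package synthesizes them by mixing Zernike modes through a seeded random
near-identity matrix (off-diagonal scale = `coupling_strength`, default
0.1) and re-orthonormalizing. The commanded→realized coupling matrix is
stored so the simulated mirror reproduces the cross-talk: commanding one
"mirror mode" excites neighbours exactly as the basis was mixed.

The reduced-scale default basis holds 6 modes — oblique/vertical
astigmatism, x/y coma, primary spherical, and trefoil (Wyant indices
4–9) — i.e. the lowest aberrations above tilt and defocus, which are
handled by stage/focus control on a real instrument. The full 28-mode
(or 50-mode) configuration is exposed through the same interfaces but is
not part of the tested reduced-scale protocol.

## Blinking-frame simulation and segmentation

Each frame draws a Poisson number of emitters (mean 13 per 128×128-pixel
field), positions uniform laterally and in z ∈ [−1, 1] µm, photon budgets
exponential with mean 2,500, plus 10 background photons/pixel, all subject
to Poisson shot noise — the published simulation protocol. Acquisition-side
processing mirrors a real-time pipeline: a temporal median over the cycle's
frames estimates the background; candidate emissions are local maxima of
the Gaussian-smoothed (σ = 1 px), background-subtracted, plane-summed
image above a small peak threshold (12 photons); detections closer than the
isolation radius (16 px) to another detection are all discarded; crops
clipped by the frame border are discarded; and crops with fewer than 1,500
background-subtracted photons are discarded (the published subregion
intensity threshold). The detector is a standard surrogate — the published
segmentation details live in supplementary material — and its parameters
sit in the acquisition config. Sub-resolution pairs (closer than ~4 px)
merge into a single smoothed peak rather than two detections; the
isolation rule therefore acts on resolvable pairs.

## Training-set synthesis

Training inputs must match what the network sees in the loop. Each sample
draws a coefficient direction uniformly on the unit sphere of the mode
space and a total W_rms uniformly within the network's amplitude range. In
the default "scene" sampling mode, a miniature blinking frame (96 px) is
then simulated at the acquisition emitter density under that wavefront and
passed through the *same* segmentation used at inference, so three
selection effects are reproduced exactly: crops are centred on the
brightest smoothed peak (not the emitter — at high aberration the dominant
speckle lobe sits well away from the molecule), only detections above the
peak and photon thresholds enter, and neighbouring emitters bleed into the
crop exactly as often as they do in real frames. All crops of one scene
share the scene's label; scenes yielding no detection are redrawn. An
"isolated" mode (one emitter per crop, optional selection filter) is kept
for diagnostics. Crops are normalized by their total background-subtracted
photon count; the background is not re-added. The static instrument
baseline, when configured, is added to every rendered wavefront but
excluded from the label.

## Network and training

The regressor is a residual CNN operating on the 2×32×32 biplane crop:
stride-2 3×3 convolution stages (8→16→32→64 channels) with batch
normalization and PReLU activations, residual blocks on all but the first
stage, and a 1×1-convolution head (zero-initialized) whose output is
averaged spatially into one amplitude per mirror mode (~123 k parameters).
The engine is written directly in numpy (im2col convolutions, hand-derived
backward passes, Adam) and is bit-deterministic given a seed. Training
minimizes per-mode MSE with equal weights; the learning rate steps down
(1×, 0.2×, 0.02×) over the schedule.

Three networks cover increasing distortion ranges — [0, 0.8], [0, 1.8] and
[0, 3.0] rad total W_rms. The default desk-scale protocol trains the small
network on 13,000 scene-sampled crops (24 epochs) and the medium/large
networks on 8,000 + 6,000 and 6,000 + 5,000 crops (16 epochs each), where
the second part of each mixture concentrates on the upper half of the range
(the region the network actually serves before switching hands off
downward). The medium and large networks warm-start from the previously
trained network's weights — curriculum transfer that measurably improves
high-range accuracy at this training budget. These sizes are an order of
magnitude below a production training run and bound the achievable
single-update accuracy at the top of the range (see Limitations).

## Inference, switching and the Kalman loop

Every cycle, up to 40 accepted subregions (acquired in bursts of 10
frames, up to 50 per cycle, stopping early once the budget is met) are
pushed through the currently selected network; the per-mode mean over
subregions is the measurement and the across-subregion standard error its
uncertainty. At least two subregions are required; otherwise the update is
skipped. Network switching follows the estimate magnitude plus twice its
uncertainty: the smallest range containing it is selected (boundary ties
fall to the smaller range), re-inferring the same subregions immediately;
a downward switch is rejected if the smaller network's own estimate
contradicts its range (saturation guard).

Per-mode scalar Kalman filters track the residual distortion: prediction
shifts the mean by the previously applied mirror delta and inflates the
variance by a process noise of (0.05 rad)² (absorbing mirror
nonlinearity); the update fuses the measurement with variance stderr²
floored at (0.02 rad)². The commanded correction is −gain × posterior mean
(gain 1.0). The simulated mirror realizes
`coupling @ (stroke·tanh(commanded/stroke))` with a 4 rad/mode stroke —
a smooth saturation surrogate for the nonlinear deformation response that
motivates multi-update convergence — plus optional seeded actuation noise.
The loop stops after 20 updates or once the posterior W_rms stays below
0.1 rad for two consecutive cycles; a stopped loop holds its mirror, so
residual curves are carried forward when summarizing. Radially symmetric
mirror modes shift the apparent focus; the loop compensates with a
simulated stage move using per-mode constants (e.g. −0.3 and −0.2 µm per
unit amplitude for the two spherical-family modes of a 28-mode mirror).

## Phase retrieval and mirror-mode measurement

The baseline wavefront sensor is Gerchberg–Saxton alternation over a bead
z-stack (−1.5 to 1.5 µm, 100 nm steps, 31 slices): measured amplitudes are
enforced in image space at every z (defocus applied/removed through the
angular-spectrum phase; pixels outside the measured window stay
unconstrained; amplitudes are rescaled to the model's energy per
iteration), and the support constraint is enforced in pupil space. The
retrieved phase is unwrapped over the support (unit-RMS modes exceed ±π at
the rim) and piston-removed. Mirror modes are measured as in the published
procedure: ±1-unit pokes per mode, phase retrieval of both bead stacks,
half-difference of the retrieved phases — cancelling any static baseline.

## Metric-based AO baseline

The trial-then-evaluate baseline sweeps each mode over 11 amplitudes in
[−1, 1] rad, measures the Gaussian-masked (σ = 2 px) peak signal at the
radial-symmetry centre of the bead image, fits a parabola to the five
points around the sampled argmax (a local fit; the full sweep of a peaked,
non-parabolic metric biases the vertex) and applies the vertex immediately;
passes are iterated (default 5). The mask is re-centred at every amplitude
sample. For an in-focus bead this converges in about one pass; for
volumetric blinking samples the per-repeat optima scatter strongly —
the instability that motivates the learned estimator.

## Evaluation

3D NCC is the Pearson correlation over all voxels of two stacks. Fisher
information uses the Poisson model `I_θθ' = Σ_px (∂µ/∂θ)(∂µ/∂θ')/µ` with
µ = signal + background, central differences (5 nm lateral, 10 nm axial),
and excludes pixels with signal below 10⁻⁶; the CRLB is the square root of
the inverse-matrix diagonal. Convergence statistics summarize repeated
loop runs into mean ± s.d. residual-vs-update curves and the mean fraction
of the induced level removed by the first update.

## Reduced-scale reproduction protocol

The quantitative reference experiment runs 11 induced levels
(0.25 … 2.75 rad, uniformly random direction in the 6-mode space) × 15
repeats = 165 closed-loop runs at the published acquisition statistics.
Problem sizes — 6 modes, the training-set sizes above, 50 frames/cycle —
are the package's desk-scale choices; they reproduce the qualitative
closed-loop behaviour and the end-point residual, while the single-update
compensation fraction lands at the lower edge of the published
distribution (the published experiment used far larger networks and
training corpora).

## Numerical choices and degenerate inputs

Rendering uses complex64 FFTs on the masked pupil support for frame
synthesis and complex128 for reference PSFs; energy normalization is exact
Parseval on the full FFT grid. Crop normalization floors the photon sum at
1 to avoid division blow-ups. The Kalman variance update uses the stable
product form `var·r/(var+r)`. Zero measurement stderr (duplicated crops)
is floored; an empty pupil support, even-sized median windows, coefficient
/basis mismatches, sub-2-subregion cycles and non-concave metric sweeps
all raise or warn explicitly. The quadratic-fit vertex is clipped to the
sampled interval.

## What the synthetic data does not model

Fluorophore photophysics (on/off kinetics, bleaching), drift, per-pixel
sCMOS noise, channel registration error between the two planes, structured
(non-uniform) background, and field-dependent aberrations. Passing the
suite therefore demonstrates correctness of the inference/control
machinery under the stated generative model, not performance on any real
instrument.

## Known limitations

- Single-update compensation at the top of the large network's range
  (≥ 2 rad) is bias-limited at this training scale; full compensation
  still succeeds through the Kalman iteration (median final residual
  ≈ 0.04–0.08 rad).
- The mirror surrogate (random coupling + tanh stroke) is statistically,
  not physically, motivated.
- The 28- and 50-mode configurations are exposed but untested against
  published numbers.
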