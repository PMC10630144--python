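"""Metric-based sensorless adaptive optics (system-flattening baseline).

The classic trial-then-evaluate procedure: for each mirror mode a set of
amplitudes is applied, the Gaussian-masked peak signal of the imaged bead is
measured at each, and a quadratic fit locates the optimum; modes are swept
sequentially and the whole pass is iterated.  Works robustly for an
in-focus bead but degrades on volumetric blinking samples, which is exactly
the regime the learned estimator is built for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricAOConfig",
    "radial_symmetry_center",
    "masked_peak_signal",
    "quadratic_optimum",
    "run_metric_ao",
]


@dataclass(frozen=True)
class MetricAOConfig:
    """Sweep protocol: 11 amplitudes per mode, 5 full iterations."""

    n_amplitudes: int = 11
    amplitude_span: tuple[float, float] = (-1.0, 1.0)   # radians per mode
    n_iterations: int = 5
    mask_sigma: float = 2.0                             # Gaussian mask width (px)
    fit_window: int | None = 5        # points around the argmax used in the fit

    def __post_init__(self) -> None:
        if self.n_amplitudes < 3 or self.n_amplitudes % 2 == 0:
            raise ValueError("n_amplitudes must be odd and >= 3")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def radial_symmetry_center(image: np.ndarray) -> tuple[float, float]:
    """Sub-pixel symmetry centre by the radial-symmetry (gradient-line) method.

    Intensity gradients of a radially symmetric spot point at its centre;
    the centre is the least-squares intersection of the gradient lines
    through the mid-points of 2x2 pixel cells.  Returns (x, y) = (col, row)
    in pixel coordinates.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("image must be 2D and at least 8x8")
    if np.ptp(img) == 0:
        raise ValueError("constant image has no symmetry centre")
    h, w = img.shape
    # dual-grid coordinates (mid-points of 2x2 cells)
    ym = (np.arange(h - 1) + 0.5)[:, None] * np.ones((1, w - 1))
    xm = np.ones((h - 1, 1)) * (np.arange(w - 1) + 0.5)[None, :]
    # derivatives along the two diagonals
    du = img[:-1, 1:] - img[1:, :-1]
    dv = img[:-1, :-1] - img[1:, 1:]
    du = ndimage.uniform_filter(du, size=3)
    dv = ndimage.uniform_filter(dv, size=3)
    grad2 = du * du + dv * dv
    # gradient slope in (x, y): the diagonals are rotated 45 degrees
    with np.errstate(divide="ignore", invalid="ignore"):
        m = -(dv + du) / (du - dv)
    m = np.where(np.isnan(m), 0.0, m)
    big = ~np.isfinite(m)
    m[big] = np.sign(-(dv + du))[big] * 1e6  # near-vertical lines
    # weights: gradient magnitude over distance to the rough centroid
    tot = grad2.sum()
    if tot == 0:
        raise ValueError("image has no gradient structure")
    xc0 = (xm * grad2).sum() / tot
    yc0 = (ym * grad2).sum() / tot
    dist = np.sqrt((xm - xc0) ** 2 + (ym - yc0) ** 2) + 0.5
    wgt = grad2 / dist
    # least squares intersection of y - ym = m (x - xm)
    wm2p1 = wgt / (m * m + 1.0)
    sw = wm2p1.sum()
    smmw = (m * m * wm2p1).sum()
    smw = (m * wm2p1).sum()
    smbw = (m * (ym - m * xm) * wm2p1).sum()
    sbw = ((ym - m * xm) * wm2p1).sum()
    det = smw * smw - smmw * sw
    xc = (smbw * sw - smw * sbw) / det
    yc = (smbw * smw - smmw * sbw) / det
    return float(xc), float(yc)


def masked_peak_signal(image: np.ndarray, center: tuple[float, float],
                       sigma: float) -> float:
    """Total intensity of the image under a unit-peak Gaussian mask at
    ``center`` (x, y); linear in the image."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    xc, yc = center
    if not (0 <= xc <= w - 1 and 0 <= yc <= h - 1):
        raise ValueError("mask centre lies outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.exp(-((xx - xc) ** 2 + (yy - yc) ** 2) / (2.0 * sigma ** 2))
    return float((img * mask).sum())


def quadratic_optimum(amplitudes: np.ndarray, signals: np.ndarray,
                      window: int | None = None) -> float:
    """Vertex of a least-squares parabola through (amplitude, signal) pairs.

    With ``window`` the fit is restricted to that many points around the
    sampled argmax (a local fit is robust when the metric curve is peaked
    rather than globally parabolic).  If the fitted curvature admits no
    maximum, the sampled argmax is returned with a warning.
    """
    a = np.asarray(amplitudes, float)
    s = np.asarray(signals, float)
    if a.size < 3:
        raise ValueError("at least 3 amplitude samples are required")
    if np.unique(a).size != a.size:
        raise ValueError("amplitudes must be distinct")
    if window is not None and window < a.size:
        order = np.argsort(a)
        a, s = a[order], s[order]
        i = int(np.argmax(s))
        lo = np.clip(i - window // 2, 0, a.size - window)
        a, s = a[lo:lo + window], s[lo:lo + window]
    c2, c1, _ = np.polyfit(a, s, 2)
    if c2 >= 0:
        warnings.warn("no concave optimum in the sweep; returning the "
                      "sampled argmax")
        return float(a[np.argmax(s)])
    vertex = -c1 / (2.0 * c2)
    # keep the vertex inside the sampled interval
    return float(np.clip(vertex, a.min(), a.max()))


def run_metric_ao(scene, basis_n_modes: int, config: MetricAOConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[np.ndarray, dict]:
    """Sequential per-mode sweep with quadratic optima, iterated.

    ``scene(commanded: np.ndarray) -> image`` renders the sample under a
    commanded mirror state (it may be stochastic for blinking samples).
    Optima are applied immediately within a pass; the history records the
    per-mode optimum of every iteration and the total number of metric
    evaluations (n_modes * n_amplitudes * n_iterations).
    """
    commanded = np.zeros(basis_n_modes)
    amps = np.linspace(*config.amplitude_span, config.n_amplitudes)
    history = {"optima": np.zeros((config.n_iterations, basis_n_modes)),
               "n_evaluations": 0}
    for it in range(config.n_iterations):
        for mode in range(basis_n_modes):
            signals = np.empty(config.n_amplitudes)
            for i, a in enumerate(amps):
                trial = commanded.copy()
                trial[mode] += a
                image = scene(trial)
                center = radial_symmetry_center(image)
                signals[i] = masked_peak_signal(image, center,
                                                config.mask_sigma)
                history["n_evaluations"] += 1
            opt = quadratic_optimum(amps, signals, window=config.fit_window)
            commanded[mode] += opt
            history["optima"][it, mode] = opt
    return commanded, history
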