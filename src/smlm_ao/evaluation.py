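"""Quantitative evaluation: PSF similarity, localization information content
and closed-loop convergence statistics.

``ncc3d`` scores the similarity of two through-focus PSF stacks; the Fisher
information / Cramér-Rao machinery quantifies the best achievable 3D
localization precision for a Poisson camera model; and
``convergence_statistics`` summarizes repeated closed-loop runs into
mean +- s.d. residual curves and the fraction of the induced distortion
removed by the first mirror update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .control import LoopTrace
from .optics import PSFStack

__all__ = [
    "ConvergenceSummary",
    "ncc3d",
    "fisher_information",
    "convergence_statistics",
    "plot_convergence",
]


@dataclass
class ConvergenceSummary:
    """Residual-vs-update statistics of repeated runs at several levels."""

    levels: np.ndarray                 # induced W_rms grid
    mean: np.ndarray                   # (n_levels, n_updates+1) mean residual
    std: np.ndarray                    # matching s.d.
    one_update_fraction: float         # mean fraction removed by update 1
    one_update_fraction_std: float
    n_traces: int

    def __post_init__(self) -> None:
        if self.n_traces >= 2 and np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")


def ncc3d(stack_a: PSFStack | np.ndarray, stack_b: PSFStack | np.ndarray
          ) -> float:
    """Pearson correlation over all voxels of two equally shaped stacks."""
    a = np.asarray(stack_a.images if isinstance(stack_a, PSFStack)
                   else stack_a, float).ravel()
    b = np.asarray(stack_b.images if isinstance(stack_b, PSFStack)
                   else stack_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("stacks must have identical shapes")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance stack has no defined correlation")
    return float(np.dot(a, b) / (na * nb))


def fisher_information(psf_model, photons: float, background: float,
                       z_grid: np.ndarray, dxy: float = 5.0,
                       dz: float = 10.0, mu_floor: float = 1e-6
                       ) -> dict[str, np.ndarray]:
    """Poisson Fisher information and CRLB for 3D localization.

    ``psf_model(x, y, z)`` must return the expected *signal* image(s) (any
    shape; biplane models return (2, S, S)) for an emitter with unit total
    intensity; images are scaled by ``photons`` and offset by ``background``
    to form the Poisson rate mu.  Derivatives are central differences with
    steps ``dxy`` (nm, lateral) and ``dz`` (nm, axial); pixels with
    mu_signal below ``mu_floor`` are excluded.  Returns per-z 3x3
    information matrices and the CRLB standard deviations per axis.
    """
    z_grid = np.atleast_1d(np.asarray(z_grid, float))
    steps = {"x": dxy, "y": dxy, "z": dz}
    info = np.zeros((z_grid.size, 3, 3))
    crlb = np.zeros((z_grid.size, 3))
    for iz, z0 in enumerate(z_grid):
        mu = photons * np.asarray(psf_model(0.0, 0.0, z0), float)
        derivs = []
        for axis in ("x", "y", "z"):
            h = steps[axis]
            args_p = {"x": 0.0, "y": 0.0, "z": z0}
            args_m = {"x": 0.0, "y": 0.0, "z": z0}
            args_p[axis] += h
            args_m[axis] -= h
            dp = np.asarray(psf_model(**args_p), float)
            dm = np.asarray(psf_model(**args_m), float)
            derivs.append(photons * (dp - dm) / (2.0 * h))
        keep = mu > mu_floor
        denom = mu + background
        mat = np.empty((3, 3))
        for i in range(3):
            for j in range(i, 3):
                v = float((derivs[i][keep] * derivs[j][keep]
                           / denom[keep]).sum())
                mat[i, j] = mat[j, i] = v
        info[iz] = mat
        if np.linalg.cond(mat) > 1e12:
            axis = "xyz"[int(np.argmin(np.diag(mat)))]
            raise np.linalg.LinAlgError(
                f"singular information matrix at z={z0:g} nm (degenerate "
                f"axis: {axis})")
        crlb[iz] = np.sqrt(np.diag(np.linalg.inv(mat)))
    return {"z": z_grid, "information": info, "crlb": crlb,
            "axial_information": info[:, 2, 2],
            "lateral_information": info[:, 0, 0]}


def convergence_statistics(traces: list[LoopTrace] | dict,
                           levels: np.ndarray | None = None
                           ) -> ConvergenceSummary:
    """Summarize repeated closed-loop runs grouped by induced level.

    ``traces`` is either a dict level -> list of LoopTrace or a flat list
    (then ``levels`` assigns one level per trace).  Residual curves shorter
    than the longest run are padded with their final value (a stopped loop
    holds its mirror).  The one-update fraction is the mean over traces of
    (induced - residual_after_first_update) / induced.
    """
    if isinstance(traces, dict):
        grouped = {float(k): list(v) for k, v in traces.items()}
    else:
        if levels is None:
            raise ValueError("a flat trace list needs per-trace levels")
        grouped = {}
        for tr, lv in zip(traces, np.asarray(levels, float)):
            grouped.setdefault(float(lv), []).append(tr)
    level_grid = np.array(sorted(grouped))
    n_updates = max(len(tr) for trs in grouped.values() for tr in trs)
    mean = np.zeros((level_grid.size, n_updates))
    std = np.zeros_like(mean)
    fractions = []
    n_traces = 0
    for il, lv in enumerate(level_grid):
        curves = []
        for tr in grouped[lv]:
            r = tr.residuals()
            if r.size < n_updates:
                r = np.concatenate([r, np.full(n_updates - r.size, r[-1])])
            curves.append(r)
            if lv > 0 and r.size >= 2:
                fractions.append((lv - r[1]) / lv)
            n_traces += 1
        curves = np.asarray(curves)
        mean[il] = curves.mean(axis=0)
        std[il] = curves.std(axis=0, ddof=1) if curves.shape[0] > 1 else 0.0
    fractions = np.asarray(fractions)
    return ConvergenceSummary(
        levels=level_grid, mean=mean, std=std,
        one_update_fraction=float(fractions.mean()) if fractions.size else 0.0,
        one_update_fraction_std=float(fractions.std(ddof=1))
        if fractions.size > 1 else 0.0,
        n_traces=n_traces)


def plot_convergence(summary: ConvergenceSummary, path: str) -> None:
    """Residual-vs-update curves (one per induced level), mean +- s.d."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    updates = np.arange(summary.mean.shape[1])
    cmap = plt.get_cmap("viridis")
    for i, lv in enumerate(summary.levels):
        color = cmap(i / max(len(summary.levels) - 1, 1))
        ax.errorbar(updates, summary.mean[i], yerr=summary.std[i],
                    color=color, label=f"{lv:.2f} rad", lw=1.2, capsize=2)
    ax.set_xlabel("mirror update")
    ax.set_ylabel(r"residual $W_{rms}$ (rad)")
    ax.legend(fontsize=7, ncol=2, title="induced level")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
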