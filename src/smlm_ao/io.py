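"""File formats: multi-page TIFF stacks with JSON sidecars, tabular truth
and loop-trace files (CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .blinking import Frame
from .control import LoopTrace
from .optics import PSFStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_frames",
    "write_truth",
    "write_trace",
]


def write_stack(path: str | Path, stack: PSFStack,
                metadata: dict | None = None) -> None:
    """Expected-value stack as 32-bit float multi-page TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.images.astype(np.float32))
    side = {"z_positions_nm": [float(z) for z in stack.z_positions]}
    side.update(metadata or {})
    path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def read_stack(path: str | Path) -> PSFStack:
    path = Path(path)
    images = tifffile.imread(path)
    side = json.loads(path.with_suffix(".json").read_text())
    return PSFStack(images=np.asarray(images, float),
                    z_positions=np.asarray(side["z_positions_nm"], float))


def write_frames(path: str | Path, frames: list[Frame]) -> None:
    """Noisy biplane frames as 16-bit unsigned multi-page TIFF.

    Pages are ordered frame-major: (frame 0 plane 0, frame 0 plane 1, ...).
    """
    pages = np.concatenate([f.pixels for f in frames], axis=0)
    tifffile.imwrite(Path(path), np.clip(pages, 0, 65535).astype(np.uint16))


def write_truth(path: str | Path, frames: list[Frame]) -> pd.DataFrame:
    """One row per simulated emitter: frame, x, y, z (nm) and photons."""
    rows = [
        {"frame": i, "x_nm": em.x, "y_nm": em.y, "z_nm": em.z,
         "photons": em.photons}
        for i, f in enumerate(frames) for em in f.truth
    ]
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "z_nm",
                                     "photons"])
    df.to_csv(Path(path), index=False)
    return df


def write_trace(path: str | Path, trace: LoopTrace,
                metadata: dict | None = None) -> None:
    trace.to_dataframe().to_csv(Path(path), index=False)
    if metadata:
        Path(path).with_suffix(".json").write_text(
            json.dumps(metadata, indent=2))
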