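"""Synthetic TIRF movie rendering: traces -> image stacks with Gaussian spots.

Each molecule is drawn as a 2-D Gaussian point-spread spot (sigma ~ 1 px)
whose integrated intensity per frame equals that molecule's trace value
above its trace background, on a constant camera background.  This is
deliberately minimal - enough to exercise the localisation and photometry
path - and is not a diffraction-limited optics simulation.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .traces import TraceSet

__all__ = ["render_movie", "write_tiff", "read_tiff"]


def _gaussian_spot(shape, x0, y0, sigma):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    g = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))
    return g / (2.0 * np.pi * sigma**2)


def render_movie(
    traces: TraceSet,
    positions: Sequence[Tuple[float, float]],
    shape: Tuple[int, int] = (64, 64),
    background: float = 0.0,
    sigma: float = 1.0,
    subtract: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render (stack_DD, stack_DA) from a trace set.

    ``subtract`` is removed from each trace value before rendering (pass
    the trace's own background level so the spot carries only the emission
    above background).  Spot kernels are truncated at 6 sigma.
    """
    if len(positions) != len(traces):
        raise ValueError("one position per trace required")
    n_frames = traces[0].n_frames
    stack_DD = np.full((n_frames, *shape), float(background))
    stack_DA = np.full((n_frames, *shape), float(background))
    for tr, (x0, y0) in zip(traces, positions):
        kernel = _gaussian_spot(shape, x0, y0, sigma)
        dd = np.maximum(tr.DD - subtract, 0.0)
        da = np.maximum(tr.DA - subtract, 0.0)
        stack_DD += dd[:, None, None] * kernel[None, :, :]
        stack_DA += da[:, None, None] * kernel[None, :, :]
    return stack_DD, stack_DA


def write_tiff(path, stack: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, stack.astype(np.float32))


def read_tiff(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)
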