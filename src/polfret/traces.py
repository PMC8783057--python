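"""Per-molecule fluorescence time traces and apparent FRET efficiency.

The two detection channels under donor excitation are named in the
single-molecule FRET convention: ``DD`` (donor emission) and ``DA``
(acceptor emission).  The apparent FRET efficiency is the uncorrected
ratio ``E* = DA / (DA + DD)``; frames where ``DA + DD <= 0`` have no
defined E* and are reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = ["TimeTrace", "TraceSet", "compute_fret"]


def compute_fret(DD, DA):
    """Apparent FRET efficiency E* = DA/(DA+DD).

    Works on scalars or arrays.  Where the total intensity is not strictly
    positive the ratio is undefined and NaN is returned (a value, not an
    error): classification and fitting downstream skip NaN frames.  The
    ratio is scale invariant, E*(c·DD, c·DA) = E*(DD, DA) for c > 0, and is
    deliberately *not* clamped to [0, 1].
    """
    DD = np.asarray(DD, dtype=float)
    DA = np.asarray(DA, dtype=float)
    total = DD + DA
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, DA / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class TimeTrace:
    """DD/DA intensity series for one molecule on a uniform frame grid."""

    molecule_id: str
    time: np.ndarray  # frame start times, seconds
    DD: np.ndarray
    DA: np.ndarray
    t_add: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.DD = np.asarray(self.DD, dtype=float)
        self.DA = np.asarray(self.DA, dtype=float)
        if not (len(self.time) == len(self.DD) == len(self.DA)):
            raise ValueError("time, DD and DA must have equal length")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time must be strictly increasing with constant step")

    @property
    def frame_dt(self) -> float:
        if len(self.time) < 2:
            raise ValueError("frame_dt undefined for traces with < 2 frames")
        return float(self.time[1] - self.time[0])

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def E_star(self) -> np.ndarray:
        return compute_fret(self.DD, self.DA)

    @property
    def total(self) -> np.ndarray:
        return self.DD + self.DA


@dataclass
class TraceSet:
    """A collection of traces from one experiment (one field of view)."""

    traces: list = field(default_factory=list)
    frame_dt: float = 0.04
    t_add: Optional[float] = None

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterable[TimeTrace]:
        return iter(self.traces)

    def __getitem__(self, i: int) -> TimeTrace:
        return self.traces[i]

    def by_id(self) -> dict:
        return {tr.molecule_id: tr for tr in self.traces}
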