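"""Ensemble views: per-frame FRET classification, the sorted colour-coded
heat-map with molecule grouping, and post-synchronised FRET histograms.

Each bound frame is classified by apparent FRET efficiency into
donor-only [0, 0.3), fingers-open [0.3, 0.53), fingers-closed [0.53, 0.8)
or unassigned-high [0.8, 1]; frames outside binding events are unbound.
Bins are half-open with boundary values in the upper bin and the top bin
closed at 1; out-of-range ratios are clamped.  The heat-map stacks one
colour-coded row per molecule, sorted in two passes: molecules with little
KF binding before nucleotide addition are removed (group c), the remainder
sorted by the extent of binding after addition, which separates persistent
binders (group a) from polymerising molecules (group b, split into bright
and dark subgroups by whether a fingers-closed event is seen shortly after
addition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .events import BindingEvent
from .traces import TimeTrace

__all__ = [
    "FrameClass",
    "GroupRules",
    "EnsembleMatrix",
    "classify_frames",
    "binding_extent",
    "build_heatmap",
    "classify_groups",
    "postsync_fret_histogram",
    "render_heatmap",
    "BIN_EDGES",
]

BIN_EDGES = (0.0, 0.3, 0.53, 0.8, 1.0)


class FrameClass:
    """Integer codes for per-frame classification."""

    UNBOUND = 0
    DONOR_ONLY = 1
    OPEN = 2
    CLOSED = 3
    HIGH = 4

    NAMES = ("unbound", "donor_only", "open", "closed", "high_unassigned")


def classify_frames(trace: TimeTrace, events: Sequence[BindingEvent]) -> np.ndarray:
    """Per-frame class codes for one molecule.

    Frames outside detected events are unbound regardless of E*; frames
    inside events are binned by clamped E*.
    """
    codes = np.full(trace.n_frames, FrameClass.UNBOUND, dtype=np.int8)
    E = np.clip(np.nan_to_num(trace.E_star, nan=0.0), 0.0, 1.0)
    binned = np.digitize(E, BIN_EDGES[1:-1], right=False) + 1  # 1..3
    binned[E >= BIN_EDGES[3]] = FrameClass.HIGH
    for ev in events:
        codes[ev.start_frame : ev.end_frame] = binned[ev.start_frame : ev.end_frame]
    return codes


def binding_extent(
    trace: TimeTrace, events: Sequence[BindingEvent], window: Tuple[float, float]
) -> float:
    """Fraction of frames in ``window`` (seconds) covered by binding events."""
    w0, w1 = window
    dt = trace.frame_dt
    f0 = max(0, int(round(w0 / dt)))
    f1 = min(trace.n_frames, int(round(w1 / dt)))
    if f1 <= f0:
        raise ValueError(f"empty window {window}")
    bound = np.zeros(trace.n_frames, dtype=bool)
    for ev in events:
        bound[ev.start_frame : ev.end_frame] = True
    return float(bound[f0:f1].mean())


@dataclass
class GroupRules:
    """Thresholds for the molecule grouping; defaults are declared
    assumptions validated against synthetic ground truth."""

    low_binding_cutoff: float = 0.05  # pre-addition extent below which -> group c
    persistence_cutoff: float = 0.5   # tail-window extent at/above which -> group a
    tail_window: float = 20.0         # seconds at the end of the acquisition
    bright_window: float = 10.0       # seconds after t_add to look for closed events


@dataclass
class EnsembleMatrix:
    """Colour-code matrix (molecules x frames) plus ordering and groups."""

    matrix: np.ndarray
    molecule_ids: List[str]          # rows of matrix, in display order
    sort_order: List[str]            # same as molecule_ids (explicit permutation)
    group_labels: Dict[str, str]     # all molecules incl. removed group c
    t_add: Optional[float]
    frame_dt: float


def classify_groups(
    traces: Sequence[TimeTrace],
    events_by_mol: Dict[str, Sequence[BindingEvent]],
    t_add: float,
    rules: Optional[GroupRules] = None,
) -> Dict[str, str]:
    """Label every molecule a_persistent / b_bright / b_dark / c_low_binding."""
    if t_add is None:
        raise ValueError("t_add is required for grouping")
    rules = rules or GroupRules()
    labels: Dict[str, str] = {}
    for tr in traces:
        evs = list(events_by_mol.get(tr.molecule_id, []))
        duration = tr.n_frames * tr.frame_dt
        pre = binding_extent(tr, evs, (0.0, t_add))
        if pre < rules.low_binding_cutoff:
            labels[tr.molecule_id] = "c_low_binding"
            continue
        tail0 = max(t_add, duration - rules.tail_window)
        tail = binding_extent(tr, evs, (tail0, duration))
        if tail >= rules.persistence_cutoff:
            labels[tr.molecule_id] = "a_persistent"
            continue
        codes = classify_frames(tr, evs)
        f0 = int(round(t_add / tr.frame_dt))
        f1 = min(tr.n_frames, int(round((t_add + rules.bright_window) / tr.frame_dt)))
        bright = bool(np.any(codes[f0:f1] == FrameClass.CLOSED))
        labels[tr.molecule_id] = "b_bright" if bright else "b_dark"
    return labels


def build_heatmap(
    traces: Sequence[TimeTrace],
    events_by_mol: Dict[str, Sequence[BindingEvent]],
    t_add: float,
    rules: Optional[GroupRules] = None,
    least_binding_first: bool = True,
) -> EnsembleMatrix:
    """Assemble the sorted ensemble matrix.

    Molecules below the pre-addition binding cutoff (group c) are removed
    from the displayed stack; the remainder are sorted by post-addition
    binding extent (ascending by default, i.e. least binding at the lowest
    row index).  Ties are broken by molecule id, so the ordering is a pure
    function of the extents and invariant to input order.
    """
    if not traces:
        raise ValueError("need at least one molecule")
    rules = rules or GroupRules()
    labels = classify_groups(traces, events_by_mol, t_add, rules)
    duration = traces[0].n_frames * traces[0].frame_dt
    kept = [tr for tr in traces if labels[tr.molecule_id] != "c_low_binding"]
    extents = {
        tr.molecule_id: binding_extent(
            tr, list(events_by_mol.get(tr.molecule_id, [])), (t_add, duration)
        )
        for tr in kept
    }
    kept.sort(
        key=lambda tr: (extents[tr.molecule_id], tr.molecule_id),
        reverse=not least_binding_first,
    )
    if kept:
        matrix = np.stack(
            [classify_frames(tr, list(events_by_mol.get(tr.molecule_id, []))) for tr in kept]
        )
    else:
        matrix = np.zeros((0, traces[0].n_frames), dtype=np.int8)
    ids = [tr.molecule_id for tr in kept]
    return EnsembleMatrix(
        matrix=matrix,
        molecule_ids=ids,
        sort_order=list(ids),
        group_labels=labels,
        t_add=t_add,
        frame_dt=traces[0].frame_dt,
    )


@dataclass
class PostsyncHistogram:
    counts: np.ndarray  # time bins x E bins
    t_edges: np.ndarray
    E_edges: np.ndarray
    n_events: int

    @property
    def empty(self) -> bool:
        return self.n_events == 0


def postsync_fret_histogram(
    events: Sequence[BindingEvent],
    traces_by_id: Dict[str, TimeTrace],
    begins_closed_only: bool = False,
    t_bins: Optional[np.ndarray] = None,
    E_bins: Optional[np.ndarray] = None,
) -> PostsyncHistogram:
    """2-D (time-since-binding x E*) histogram of post-synchronised events."""
    sel = [ev for ev in events if (ev.begins_closed or not begins_closed_only)]
    if t_bins is None:
        t_bins = np.arange(0.0, 8.0 + 1e-9, 0.04)
    if E_bins is None:
        E_bins = np.linspace(-0.1, 1.1, 61)
    tvals: List[float] = []
    evals: List[float] = []
    for ev in sel:
        tr = traces_by_id[ev.molecule_id]
        E = tr.E_star[ev.start_frame : ev.end_frame]
        t_off = (np.arange(ev.n_frames)) * ev.frame_dt
        ok = np.isfinite(E)
        tvals.extend(t_off[ok])
        evals.extend(E[ok])
    counts, t_edges, E_edges = np.histogram2d(tvals, evals, bins=[t_bins, E_bins])
    return PostsyncHistogram(counts, t_edges, E_edges, n_events=len(sel))


#: Fixed colour map: unbound white, donor-only blue, open green, closed red,
#: unassigned-high black.
HEATMAP_COLOURS = ("white", "#2060c0", "#20a040", "#d03020", "black")


def render_heatmap(matrix: EnsembleMatrix, path=None):
    """Raster rendering of an ensemble matrix; returns the Matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if matrix.matrix.size == 0:
        raise ValueError("matrix is empty")
    cmap = ListedColormap(HEATMAP_COLOURS)
    norm = BoundaryNorm(np.arange(-0.5, 5.5), cmap.N)
    n_mol, n_frames = matrix.matrix.shape
    fig, ax = plt.subplots(figsize=(8, max(2, n_mol * 0.04)))
    ax.imshow(
        matrix.matrix,
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        norm=norm,
        origin="lower",
        extent=(0, n_frames * matrix.frame_dt, 0, n_mol),
    )
    if matrix.t_add is not None:
        ax.axvline(matrix.t_add, color="k", linestyle=":", linewidth=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("DNA molecule (sorted)")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
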