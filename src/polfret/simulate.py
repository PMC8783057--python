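"""Generative model of the TIRF polymerase-fingers experiment.

Simulates, per immobilised DNA molecule, the continuous-time state path of
Klenow-fragment (KF) binding and fingers dynamics, then renders it into
camera-frame DD/DA intensity traces with realistic photophysics.

Kinetic model
-------------
An unbound DNA binds KF with a pseudo-first-order rate (KF concentration
folded in).  A bound binary complex interconverts between the fingers-open
(E* ~ 0.4) and fingers-closed (E* ~ 0.6) conformation and can dissociate
from either.  Once nucleotides are present (after ``t_add``) a bound
complex runs the nucleotide-addition cycle: a fingers-open wait for dNTP
binding (rate proportional to [dNTP]), fingers-closed incorporation (one
exponential dwell per added base, rate depending on the templating base),
repeated until the template permits no further additions; the extended
(blunt or short-overhang) DNA then reverts to binary-complex dynamics with
a larger dissociation rate.

All dwell draws are exact (Gillespie); the nucleotide-addition time
``t_add`` is handled by truncating the pending dwell at the boundary and
redrawing under the new rate set, which is exact for memoryless kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._rng import rng_for
from .traces import TimeTrace, TraceSet

__all__ = [
    "KineticScheme",
    "PhotophysicsModel",
    "StatePath",
    "simulate_state_path",
    "apply_photophysics",
    "render_trace",
    "simulate_experiment",
    "sample_extension_dwells",
    "apparent_fret",
    "DEFAULT_TEMPLATE",
]

# Templating bases (5'->3') read by the polymerase.  The first ten are the
# complements of the incorporated run T-A-T-T-A-G-T-G-A-T used in the 5- and
# 10-nt extension experiments; the final five are synthetic filler chosen to
# include every base type.
DEFAULT_TEMPLATE = "ATAATCACTAGCGTC"

#: Default per-templating-base incorporation rates (s^-1); keyed by the
#: *templating* base, i.e. "A" is the rate of dTTP incorporation.
DEFAULT_INCORPORATION_RATES: Dict[str, float] = {
    "A": 3.4,  # dTTP
    "T": 2.0,  # dATP
    "G": 1.0,  # dCTP
    "C": 1.5,  # dGTP
}

_BOUND_LABELS = frozenset({"open", "closed", "bound_dark", "bound_donor_only"})


@dataclass
class KineticScheme:
    """Rate constants of the KF binding / fingers / polymerisation scheme.

    All rates are per second.  ``incorporation_rates`` is keyed by the
    templating base; ``template_sequence`` lists the templating bases 5'->3';
    ``n_max`` is how many additions the experiment's dNTP subset permits.
    ``t_add`` is the mid-acquisition nucleotide-addition time (``None`` for
    nucleotide-free experiments, 0.0 for nucleotides present throughout).
    """

    binding_rate: float = 0.05
    unbinding_rate_pre: float = 0.1  # mean bound time ~10 s pre-nucleotide
    unbinding_rate_post: float = 0.5
    k_close: float = 1.4
    k_open: float = 5.3
    dntp_wait_rate: float = 50.0
    incorporation_rates: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INCORPORATION_RATES)
    )
    n_max: int = 0
    template_sequence: str = DEFAULT_TEMPLATE
    t_add: Optional[float] = None

    def validate(self) -> None:
        rates = [
            self.binding_rate,
            self.unbinding_rate_pre,
            self.unbinding_rate_post,
            self.k_close,
            self.k_open,
            self.dntp_wait_rate,
            *self.incorporation_rates.values(),
        ]
        for r in rates:
            if not math.isfinite(r) or r < 0:
                raise ValueError(f"rates must be finite and >= 0, got {r!r}")
        if self.n_max < 0 or self.n_max > len(self.template_sequence):
            raise ValueError(
                f"n_max ({self.n_max}) must be within the template length "
                f"({len(self.template_sequence)})"
            )
        if self.n_max > 0:
            bases = set(self.template_sequence[: self.n_max])
            missing = bases - set(self.incorporation_rates)
            if missing:
                raise ValueError(f"no incorporation rate for bases {sorted(missing)}")
        if self.t_add is not None and self.t_add < 0:
            raise ValueError("t_add must be >= 0 (or None)")


@dataclass
class PhotophysicsModel:
    """Camera / dye model used to render a state path into DD/DA frames."""

    frame_dt: float = 0.04
    I_total: float = 600.0
    E_open: float = 0.4
    E_closed: float = 0.6
    E_donor_only: float = 0.05
    background_DD: float = 100.0
    background_DA: float = 100.0
    noise_sd: float = 40.0
    acceptor_bleach_rate: float = 0.02
    donor_bleach_rate: float = 0.01
    red_laser_window: float = 2.4
    red_excess_DA: float = 800.0
    label_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            # ~30% donor-only, ~30% acceptor-only, ~25% unlabelled KF
            "dual": 0.15,
            "donor_only": 0.30,
            "acceptor_only": 0.30,
            "unlabelled": 0.25,
        }
    )

    def validate(self) -> None:
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be > 0")
        for name in ("E_open", "E_closed", "E_donor_only"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        tot = sum(self.label_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"label_fractions must sum to 1, got {tot}")


@dataclass
class StatePath:
    """Piecewise-constant ground-truth trajectory of one molecule.

    ``segments`` is an ordered, contiguous list of
    ``(state_label, t_start, t_end)`` with labels in {unbound, open, closed,
    bound_dark, bound_donor_only}.  ``event_species`` records, for each
    binding episode in order, the label stoichiometry of the KF molecule
    that bound (set by :func:`apply_photophysics`).
    """

    segments: List[Tuple[str, float, float]]
    n_incorporated: int = 0
    incorporation_times: List[float] = field(default_factory=list)
    event_species: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = None
        for label, t0, t1 in self.segments:
            if t1 <= t0:
                raise ValueError(f"segment ({label}, {t0}, {t1}) has t_end <= t_start")
            if prev_end is not None and abs(t0 - prev_end) > 1e-9:
                raise ValueError("segments must be contiguous")
            prev_end = t1

    @property
    def duration(self) -> float:
        return self.segments[-1][2] - self.segments[0][1]

    def bound_intervals(self) -> List[Tuple[float, float]]:
        """Maximal intervals during which the molecule is KF-bound."""
        out: List[Tuple[float, float]] = []
        for label, t0, t1 in self.segments:
            if label in _BOUND_LABELS:
                if out and abs(out[-1][1] - t0) < 1e-9:
                    out[-1] = (out[-1][0], t1)
                else:
                    out.append((t0, t1))
        return out


def _merge(segments: List[Tuple[str, float, float]]) -> List[Tuple[str, float, float]]:
    out: List[Tuple[str, float, float]] = []
    for seg in segments:
        if out and out[-1][0] == seg[0] and abs(out[-1][2] - seg[1]) < 1e-12:
            out[-1] = (seg[0], out[-1][1], seg[2])
        else:
            out.append(tuple(seg))
    return out


def simulate_state_path(
    scheme: KineticScheme, duration: float, seed: int
) -> StatePath:
    """Exact stochastic simulation of one molecule's kinetic state path.

    Before ``scheme.t_add`` only binary-complex dynamics occur; afterwards
    each bound episode runs the nucleotide-addition cycle until ``n_max``
    incorporations, then switches to post-extension binding kinetics.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    scheme.validate()
    rng = rng_for(seed)
    t_add = scheme.t_add if scheme.t_add is not None else math.inf

    t = 0.0
    state = "unbound"
    n_inc = 0
    inc_times: List[float] = []
    segments: List[Tuple[str, float, float]] = []

    while t < duration:
        dntps_present = t >= t_add
        extending = dntps_present and n_inc < scheme.n_max
        extended = dntps_present and scheme.n_max > 0 and n_inc >= scheme.n_max
        unbind = scheme.unbinding_rate_post if extended else scheme.unbinding_rate_pre

        # (rate, target) pairs out of the current state; "closed*" marks an
        # incorporating closed dwell whose exit adds one base.
        if state == "unbound":
            channels = [(scheme.binding_rate, "open")]
        elif state == "open":
            if extending:
                channels = [(scheme.dntp_wait_rate, "closed*"), (unbind, "unbound")]
            else:
                channels = [(scheme.k_close, "closed"), (unbind, "unbound")]
        elif state == "closed*":
            k_inc = scheme.incorporation_rates[scheme.template_sequence[n_inc]]
            channels = [(k_inc, "open+")]
        else:  # binary closed
            channels = [(scheme.k_open, "open"), (unbind, "unbound")]

        total = sum(r for r, _ in channels)
        if total <= 0.0:
            tau = math.inf
        else:
            tau = rng.exponential(1.0 / total)

        t_next = t + tau
        # Truncate at the nucleotide-addition boundary and redraw: exact for
        # memoryless kinetics, and the rate set may change there.
        if t < t_add < min(t_next, duration):
            segments.append((_public_label(state), t, t_add))
            t = t_add
            continue
        if t_next >= duration:
            segments.append((_public_label(state), t, duration))
            break

        u = rng.uniform(0.0, total)
        acc = 0.0
        for r, target in channels:
            acc += r
            if u <= acc:
                break
        segments.append((_public_label(state), t, t_next))
        t = t_next
        if target == "open+":
            n_inc += 1
            inc_times.append(t)
            state = "open"
        else:
            state = target

    return StatePath(
        segments=_merge(segments), n_incorporated=n_inc, incorporation_times=inc_times
    )


def _public_label(state: str) -> str:
    return "closed" if state == "closed*" else state


def apply_photophysics(
    path: StatePath, phys: PhotophysicsModel, seed: int
) -> StatePath:
    """Resolve label stoichiometry and bleaching onto a kinetic state path.

    Each binding episode draws one KF molecule from ``label_fractions``.
    Acceptor-only and unlabelled KF emit nothing under donor excitation and
    their episodes become ``bound_dark``; donor-only episodes become
    ``bound_donor_only``; for dual-labelled KF an exponential acceptor
    bleach time converts the remainder of the episode to
    ``bound_donor_only`` and a donor bleach time to ``bound_dark``.
    """
    phys.validate()
    rng = rng_for(seed)
    species_names = list(phys.label_fractions.keys())
    probs = np.array([phys.label_fractions[s] for s in species_names])

    episodes = path.bound_intervals()
    species: List[str] = [
        species_names[i] for i in rng.choice(len(species_names), size=len(episodes), p=probs)
    ] if episodes else []

    def draw_bleach(rate: float) -> float:
        return rng.exponential(1.0 / rate) if rate > 0 else math.inf

    # Per-episode absolute times after which emission changes character.
    acceptor_off: List[float] = []
    donor_off: List[float] = []
    for (e0, _e1), sp in zip(episodes, species):
        acceptor_off.append(e0 + (draw_bleach(phys.acceptor_bleach_rate) if sp == "dual" else 0.0 if sp in ("acceptor_only", "unlabelled") else math.inf))
        donor_off.append(e0 + (draw_bleach(phys.donor_bleach_rate) if sp in ("dual", "donor_only") else 0.0))

    new_segments: List[Tuple[str, float, float]] = []
    for label, t0, t1 in path.segments:
        if label not in _BOUND_LABELS:
            new_segments.append((label, t0, t1))
            continue
        idx = next(
            i for i, (e0, e1) in enumerate(episodes) if e0 - 1e-9 <= t0 and t1 <= e1 + 1e-9
        )
        sp = species[idx]
        if sp in ("acceptor_only", "unlabelled"):
            new_segments.append(("bound_dark", t0, t1))
            continue
        if sp == "donor_only":
            cuts = [("bound_donor_only", donor_off[idx]), ("bound_dark", math.inf)]
        else:  # dual
            cuts = [
                (label, min(acceptor_off[idx], donor_off[idx])),
                ("bound_donor_only" if acceptor_off[idx] < donor_off[idx] else "bound_dark",
                 max(acceptor_off[idx], donor_off[idx])),
                ("bound_dark", math.inf),
            ]
        t = t0
        for lab, t_cut in cuts:
            hi = min(t1, t_cut)
            if hi > t + 1e-12:
                new_segments.append((lab, t, hi))
                t = hi
            if t >= t1 - 1e-12:
                break

    return StatePath(
        segments=_merge(new_segments),
        n_incorporated=path.n_incorporated,
        incorporation_times=list(path.incorporation_times),
        event_species=species,
    )


def apparent_fret(E: float, phys: PhotophysicsModel) -> float:
    """Apparent E* of a bound dual-labelled state after the background pedestal.

    Rendered traces carry the camera background in both channels, which
    compresses the raw ratio toward 0.5 exactly as uncorrected experimental
    E* values are compressed: (I_total·E + bg_DA) / (I_total + bg_DA + bg_DD).
    """
    return (phys.I_total * E + phys.background_DA) / (
        phys.I_total + phys.background_DA + phys.background_DD
    )


def _state_intensities(label: str, phys: PhotophysicsModel) -> Tuple[float, float]:
    """(DD, DA) emission above background for one state label."""
    if label in ("unbound", "bound_dark"):
        return 0.0, 0.0
    E = {
        "open": phys.E_open,
        "closed": phys.E_closed,
        "bound_donor_only": phys.E_donor_only,
    }[label]
    return phys.I_total * (1.0 - E), phys.I_total * E


def render_trace(
    path: StatePath,
    phys: PhotophysicsModel,
    duration: float,
    seed: int,
    molecule_id: str = "mol",
    apply_species: bool = True,
) -> TimeTrace:
    """Render a state path into camera frames.

    Each frame integrates emission over its exposure, so a frame straddling
    a state switch carries the occupancy-weighted mean intensity.  Gaussian
    camera noise is added per channel per frame; the DA channel carries the
    red-laser localisation excess for frames starting inside
    ``red_laser_window``.  Noisy intensities may go negative and are not
    clipped (camera offset subtraction can undershoot).

    With ``apply_species=True`` (default) label stoichiometry and bleaching
    are resolved first via :func:`apply_photophysics`; pass ``False`` when
    ``path`` has already been resolved.
    """
    phys.validate()
    if path.segments[0][1] > 1e-9 or path.segments[-1][2] < duration - 1e-9:
        raise ValueError("path must cover [0, duration]")
    if apply_species:
        path = apply_photophysics(path, phys, seed)
    rng = rng_for(seed, 1)

    dt = phys.frame_dt
    n_frames = int(round(duration / dt))
    DD = np.zeros(n_frames)
    DA = np.zeros(n_frames)
    for label, t0, t1 in path.segments:
        i_dd, i_da = _state_intensities(label, phys)
        if i_dd == 0.0 and i_da == 0.0:
            continue
        f0 = max(0, int(math.floor(t0 / dt + 1e-12)))
        f1 = min(n_frames, int(math.ceil(t1 / dt - 1e-12)))
        if f1 <= f0:
            continue
        starts = np.arange(f0, f1) * dt
        overlap = np.minimum(starts + dt, t1) - np.maximum(starts, t0)
        frac = np.clip(overlap / dt, 0.0, 1.0)
        DD[f0:f1] += i_dd * frac
        DA[f0:f1] += i_da * frac

    DD += phys.background_DD
    DA += phys.background_DA
    time = np.arange(n_frames) * dt
    DA[time < phys.red_laser_window] += phys.red_excess_DA
    if phys.noise_sd > 0:
        DD = DD + rng.normal(0.0, phys.noise_sd, n_frames)
        DA = DA + rng.normal(0.0, phys.noise_sd, n_frames)
    return TimeTrace(molecule_id=molecule_id, time=time, DD=DD, DA=DA)


def simulate_experiment(
    scheme: KineticScheme,
    phys: PhotophysicsModel,
    n_molecules: int,
    duration: float,
    contaminant_fraction: float = 0.0,
    no_binding_fraction: float = 0.0,
    seed: int = 0,
) -> Tuple[TraceSet, List[StatePath]]:
    """Simulate a field of view of ``n_molecules`` immobilised DNAs.

    A ``contaminant_fraction`` of molecules are "persistent binders":
    surface-adsorbed KF showing long, nucleotide-independent binding.  A
    ``no_binding_fraction`` show background only (unbindable DNA).  The
    remaining molecules follow ``scheme``.  Returns the rendered traces and
    the photophysics-resolved ground-truth paths (same order).
    """
    for name, f in (("contaminant_fraction", contaminant_fraction),
                    ("no_binding_fraction", no_binding_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if contaminant_fraction + no_binding_fraction > 1.0 + 1e-12:
        raise ValueError("contaminant_fraction + no_binding_fraction must be <= 1")
    scheme.validate()
    phys.validate()

    # Persistent binders: essentially permanent, dNTP-blind binding with
    # binary-complex fingers dynamics.
    contaminant_scheme = replace(
        scheme,
        binding_rate=2.0,
        unbinding_rate_pre=0.005,
        unbinding_rate_post=0.005,
        n_max=0,
        t_add=None,
    )
    dead_scheme = replace(scheme, binding_rate=0.0, n_max=0, t_add=None)

    rng = rng_for(seed, 0)
    kinds = rng.choice(
        3,
        size=n_molecules,
        p=[contaminant_fraction, no_binding_fraction,
           1.0 - contaminant_fraction - no_binding_fraction],
    )

    traces: List[TimeTrace] = []
    paths: List[StatePath] = []
    for m in range(n_molecules):
        mol_scheme = (contaminant_scheme, dead_scheme, scheme)[kinds[m]]
        raw = simulate_state_path(mol_scheme, duration, seed=_sub(seed, m, 1))
        resolved = apply_photophysics(raw, phys, seed=_sub(seed, m, 2))
        trace = render_trace(
            resolved, phys, duration, seed=_sub(seed, m, 3),
            molecule_id=f"mol{m:04d}", apply_species=False,
        )
        trace.t_add = scheme.t_add
        traces.append(trace)
        paths.append(resolved)

    return TraceSet(traces=traces, frame_dt=phys.frame_dt, t_add=scheme.t_add), paths


def _sub(seed: int, *keys: int) -> int:
    # Stable scalar sub-seed for operations that take an integer seed.
    return int(np.random.SeedSequence((int(seed), *keys)).generate_state(1)[0])


def sample_extension_dwells(
    n_bases: int, rates, reps: int, seed: int = 0
) -> np.ndarray:
    """Draw ``reps`` total polymerisation times for an ``n_bases`` extension.

    Each sample is the sum of independent exponential dwells, one per base;
    ``rates`` gives the per-base rates (a scalar is broadcast).  With equal
    rates the samples follow a gamma(n_bases, rate) distribution.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (n_bases,))
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        raise ValueError("all rates must be finite and > 0")
    rng = rng_for(seed)
    return rng.exponential(1.0 / rates, size=(reps, n_bases)).sum(axis=1)
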