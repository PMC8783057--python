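"""Frame classification, heat-map sorting/grouping, post-sync histograms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import polfret as pf
from polfret.ensemble import BIN_EDGES, FrameClass, PostsyncHistogram


def trace_with_E(E_values, total=800.0, frame_dt=0.04, mol="m0"):
    E = np.asarray(E_values, dtype=float)
    return pf.TimeTrace(
        molecule_id=mol,
        time=np.arange(len(E)) * frame_dt,
        DD=total * (1 - E),
        DA=total * E,
    )


def full_event(trace):
    return pf.BindingEvent(
        molecule_id=trace.molecule_id,
        start_frame=0,
        end_frame=trace.n_frames,
        frame_dt=trace.frame_dt,
    )


class TestClassifyFrames:
    def test_open_and_closed_bins(self):
        tr = trace_with_E([0.4, 0.6, 0.1, 0.9])
        codes = pf.classify_frames(tr, [full_event(tr)])
        assert list(codes) == [
            FrameClass.OPEN, FrameClass.CLOSED, FrameClass.DONOR_ONLY, FrameClass.HIGH,
        ]

    def test_frames_outside_events_are_unbound(self):
        tr = trace_with_E([0.6] * 10)
        ev = pf.BindingEvent(
            molecule_id="m0", start_frame=3, end_frame=7, frame_dt=0.04
        )
        codes = pf.classify_frames(tr, [ev])
        assert np.all(codes[:3] == FrameClass.UNBOUND)
        assert np.all(codes[3:7] == FrameClass.CLOSED)
        assert np.all(codes[7:] == FrameClass.UNBOUND)

    @given(E=st.floats(0.0, 1.0))
    def test_bins_partition_unit_interval(self, E):
        tr = trace_with_E([E, E])
        codes = pf.classify_frames(tr, [full_event(tr)])
        assert codes[0] in (
            FrameClass.DONOR_ONLY, FrameClass.OPEN, FrameClass.CLOSED, FrameClass.HIGH,
        )
        # boundary values go to the upper bin
        for lo, code in zip(BIN_EDGES[1:-1], (FrameClass.OPEN, FrameClass.CLOSED, FrameClass.HIGH)):
            if E == lo:
                assert codes[0] == code

    def test_out_of_range_E_clamped(self):
        tr = trace_with_E([-0.4, 1.6])
        codes = pf.classify_frames(tr, [full_event(tr)])
        assert codes[0] == FrameClass.DONOR_ONLY and codes[1] == FrameClass.HIGH


class TestBindingExtent:
    def test_no_events_zero(self):
        tr = trace_with_E([0.5] * 100)
        assert pf.binding_extent(tr, [], (0.0, 4.0)) == 0.0

    def test_fully_bound_one(self):
        tr = trace_with_E([0.5] * 100)
        assert pf.binding_extent(tr, [full_event(tr)], (0.0, 4.0)) == 1.0

    def test_partial_coverage(self):
        tr = trace_with_E([0.5] * 250)  # 10 s
        ev = pf.BindingEvent("m0", 0, 75, 0.04)  # 3 s of a 10 s window
        assert pf.binding_extent(tr, [ev], (0.0, 10.0)) == pytest.approx(0.3)

    def test_empty_window_rejected(self):
        tr = trace_with_E([0.5] * 100)
        with pytest.raises(ValueError):
            pf.binding_extent(tr, [], (2.0, 2.0))


def make_population(n, bound_pre, bound_post, seed=0, n_frames=500, dt=0.04):
    """Molecules bound for the given extents before/after t_add = 10 s."""
    traces, events = [], {}
    for i in range(n):
        mol = f"m{i:03d}"
        tr = trace_with_E(np.full(n_frames, 0.6), mol=mol)
        evs = []
        split = 250
        n_pre = int(split * bound_pre[i])
        if n_pre > 0:
            evs.append(pf.BindingEvent(mol, 0, n_pre, dt))
        n_post = int(250 * bound_post[i])
        if n_post > 0:
            evs.append(pf.BindingEvent(mol, split, split + n_post, dt))
        traces.append(tr)
        events[mol] = evs
    return traces, events


class TestBuildHeatmap:
    T_ADD = 10.0

    def test_all_low_binding_gives_empty_stack(self):
        traces, events = make_population(4, [0.0] * 4, [0.0] * 4)
        m = pf.build_heatmap(traces, events, self.T_ADD)
        assert m.matrix.shape[0] == 0
        assert all(v == "c_low_binding" for v in m.group_labels.values())

    def test_sorted_by_post_addition_extent(self):
        traces, events = make_population(2, [0.8, 0.8], [0.8, 0.2])
        m = pf.build_heatmap(traces, events, self.T_ADD)
        assert m.sort_order == ["m001", "m000"]  # least post binding first

    def test_sort_is_permutation_invariant(self):
        rng = np.random.default_rng(3)
        pre = rng.uniform(0.2, 1.0, 12)
        post = rng.uniform(0.0, 1.0, 12)
        traces, events = make_population(12, pre, post)
        m1 = pf.build_heatmap(traces, events, self.T_ADD)
        m2 = pf.build_heatmap(traces[::-1], events, self.T_ADD)
        assert m1.sort_order == m2.sort_order

    def test_non_binder_fraction_recovered(self, clean_phys):
        f_dead = 0.3
        sch = pf.KineticScheme(n_max=0, t_add=40.0, binding_rate=0.1)
        traces, _paths = pf.simulate_experiment(
            sch, clean_phys, n_molecules=150, duration=80.0,
            no_binding_fraction=f_dead, seed=21,
        )
        events = {}
        for tr in traces:
            thr = pf.adaptive_threshold(tr)
            events[tr.molecule_id] = pf.detect_events(
                tr, thr, exclude_before=clean_phys.red_laser_window
            )
        m = pf.build_heatmap(list(traces), events, t_add=40.0)
        n_c = sum(v == "c_low_binding" for v in m.group_labels.values())
        sigma = np.sqrt(150 * f_dead * (1 - f_dead))
        assert abs(n_c - 150 * f_dead) < 3 * sigma


class TestClassifyGroups:
    T_ADD = 10.0

    def test_persistent_binder(self):
        traces, events = make_population(1, [0.9], [1.0])
        labels = pf.classify_groups(traces, events, self.T_ADD)
        assert labels["m000"] == "a_persistent"

    def test_bright_polymeriser(self):
        # closed event right after addition, binding then decays
        traces, events = make_population(1, [0.9], [0.2])
        labels = pf.classify_groups(traces, events, self.T_ADD)
        assert labels["m000"] == "b_bright"

    def test_dark_polymeriser(self):
        traces, events = make_population(1, [0.9], [0.0])
        labels = pf.classify_groups(traces, events, self.T_ADD)
        assert labels["m000"] == "b_dark"


class TestPostsyncFretHistogram:
    def test_constant_E_in_single_column(self):
        tr = trace_with_E([0.65] * 50)
        h = pf.postsync_fret_histogram([full_event(tr)], {"m0": tr})
        col_mass = h.counts.sum(axis=0)
        assert (col_mass > 0).sum() == 1

    def test_begins_closed_filter_can_empty(self):
        tr = trace_with_E([0.4] * 50)
        ev = full_event(tr)  # begins open
        h = pf.postsync_fret_histogram([ev], {"m0": tr}, begins_closed_only=True)
        assert h.empty and h.counts.sum() == 0

    def test_extension_ensemble_relaxes_toward_open(self, clean_phys):
        sch = pf.KineticScheme(
            n_max=5, t_add=0.0, dntp_wait_rate=50.0, unbinding_rate_post=0.3,
            binding_rate=0.1,
        )
        traces, _ = pf.simulate_experiment(sch, clean_phys, 120, 60.0, seed=13)
        events = []
        by_id = {}
        for tr in traces:
            thr = pf.adaptive_threshold(tr)
            evs = pf.detect_events(tr, thr, exclude_before=clean_phys.red_laser_window)
            events.extend(evs)
            by_id[tr.molecule_id] = tr
        h = pf.postsync_fret_histogram(events, by_id, begins_closed_only=True)
        assert h.n_events >= 20
        centers_E = 0.5 * (h.E_edges[:-1] + h.E_edges[1:])
        t_centers = 0.5 * (h.t_edges[:-1] + h.t_edges[1:])

        def col_mean(sl):
            w = h.counts[sl].sum(axis=0)
            return np.sum(w * centers_E) / w.sum()

        early = col_mean(t_centers < 0.5)
        late = col_mean((t_centers > 3.0) & (t_centers < 6.0))
        assert early > 0.52  # starts near the closed level
        assert late < early - 0.05  # relaxes toward open


class TestRenderHeatmap:
    def test_rendered_colours_deterministic(self, tmp_path):
        traces, events = make_population(3, [0.8, 0.6, 0.9], [0.1, 0.5, 0.9])
        m = pf.build_heatmap(traces, events, 10.0)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        pf.render_heatmap(m, p1)
        pf.render_heatmap(m, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_matrix_rejected(self):
        traces, events = make_population(2, [0.0, 0.0], [0.0, 0.0])
        m = pf.build_heatmap(traces, events, 10.0)
        with pytest.raises(ValueError):
            pf.render_heatmap(m)
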