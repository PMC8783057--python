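"""Dwell-rate estimators, hypoexponential fits, decay fits, derived values."""

import numpy as np
import pytest
from scipy import integrate, stats

import polfret as pf
from polfret.hmm import Dwell
from polfret.kinetics import (
    DwellHistogram,
    fit_geometric_rate,
    hypoexp_pdf,
    _hypoexp_grid,
)


def make_dwells(durations, censored=None, label="closed"):
    censored = censored or [False] * len(durations)
    return [
        Dwell("m", 0, label, d, False, c, 0.0) for d, c in zip(durations, censored)
    ]


class TestFitExponentialRate:
    def test_uncensored_equals_inverse_mean_exactly(self):
        durations = [0.2, 0.5, 1.1, 0.7, 0.3, 0.9, 0.25, 0.6, 0.45, 0.8]
        est = pf.fit_exponential_rate(make_dwells(durations), t_min=0.0, n_boot=50)
        assert est.rate == pytest.approx(1.0 / np.mean(durations), rel=1e-12)

    def test_quantised_dwells_recover_rate_within_3se(self):
        # 1e4 exponential dwells at 3.4/s, quantised to 40-ms frames; the
        # discrete (geometric) likelihood with 2-frame truncation removes
        # quantisation and short-dwell undercount bias.
        rng = np.random.default_rng(0)
        dt = 0.04
        t = np.round(rng.exponential(1 / 3.4, 10_000) / dt) * dt
        t = t[t >= 2 * dt]
        est = fit_geometric_rate(t, frame_dt=dt, n_min=2, n_boot=300, seed=1)
        assert abs(est.rate - 3.4) < 3 * est.stderr
        # The continuous left-truncated MLE on rounded data overestimates
        # (rounding shrinks the conditional excess); at k*dt ~ 0.14 the bias
        # stays under ~10%, which is why the geometric variant exists.
        est_c = pf.fit_exponential_rate(t, t_min=2 * dt, n_boot=50, seed=1)
        assert 3.4 < est_c.rate < 3.4 * 1.10

    def test_survival_terms_remove_censoring_bias(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1 / 2.0, 4000)
        cutoff = 0.6
        obs = np.minimum(t, cutoff)
        cens = t >= cutoff
        est = pf.fit_exponential_rate(
            np.column_stack([obs, cens]), policy="survival", n_boot=200, seed=2
        )
        assert abs(est.rate - 2.0) < 3 * est.stderr

    def test_all_censored_rejected(self):
        dwells = make_dwells([0.5] * 20, censored=[True] * 20)
        with pytest.raises(ValueError):
            pf.fit_exponential_rate(dwells, n_boot=10)

    def test_drop_censored_policy_needs_uncensored(self):
        dwells = make_dwells([0.5] * 20, censored=[True] * 20)
        with pytest.raises(ValueError, match="too few|censored"):
            pf.fit_exponential_rate(dwells, policy="drop-censored", n_boot=10)

    def test_too_few_dwells_error_names_count(self):
        with pytest.raises(ValueError, match="3"):
            pf.fit_exponential_rate(make_dwells([0.5, 0.4, 0.6]), n_boot=10)


class TestFirstClosedDwell:
    def test_begin_closed_event(self):
        dwells = make_dwells([1.5], label="closed") + make_dwells([3.0], label="open")
        fc = pf.first_closed_dwell(dwells, frame_dt=0.04)
        assert fc.duration == pytest.approx(1.5) and not fc.censored

    def test_begin_open_fails_filter(self):
        dwells = [
            Dwell("m", 0, "open", 2.0, True, False, 0.0),
            Dwell("m", 0, "closed", 1.0, False, True, 2.0),
        ]
        assert pf.first_closed_dwell(dwells, frame_dt=0.04) is None

    def test_single_frame_open_start_tolerated(self):
        dwells = [
            Dwell("m", 0, "open", 0.04, True, False, 0.0),
            Dwell("m", 0, "closed", 1.5, False, True, 0.04),
        ]
        fc = pf.first_closed_dwell(dwells, frame_dt=0.04, start_tolerance_frames=1)
        assert fc.duration == pytest.approx(1.5) and fc.censored


class TestPolymerisationTimeHistogram:
    def test_mean_of_simple_sample(self):
        h = pf.polymerisation_time_histogram([1.0, 2.0, 3.0])
        assert h.mean == pytest.approx(2.0)
        assert h.counts.sum() == 3

    def test_gamma_sample_mean_within_3se(self):
        s = pf.sample_extension_dwells(5, [3.2] * 5, reps=10_000, seed=4)
        h = pf.polymerisation_time_histogram(s)
        se = s.std(ddof=1) / np.sqrt(s.size)
        assert abs(h.mean - 5 / 3.2) < 3 * se

    def test_return_to_open_filter_can_empty(self):
        h = pf.polymerisation_time_histogram(
            [1.0, 2.0], return_to_open_flags=[False, False], return_to_open_only=True
        )
        assert h.empty and np.isnan(h.mean)


class TestHypoexponential:
    def test_density_integrates_to_one(self):
        rates = np.array([3.4, 2.0, 1.0, 1.5])
        val, _err = integrate.quad(lambda t: hypoexp_pdf(t, rates)[0], 0, 200, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_equal_rates_reduce_to_gamma(self):
        t = np.linspace(0.01, 5, 200)
        ours = hypoexp_pdf(t, [3.2] * 5)
        oracle = stats.gamma(a=5, scale=1 / 3.2).pdf(t)
        assert np.allclose(ours, oracle, rtol=1e-3, atol=1e-4)

    def test_partial_fraction_agrees_with_grid_convolution(self):
        rates = np.array([3.4, 2.0, 1.0, 1.5])
        t = np.linspace(0.05, 8, 100)
        closed_form = hypoexp_pdf(t, rates)
        grid_t, grid_f = _hypoexp_grid(rates, t_max=8.0)
        assert np.allclose(closed_form, np.interp(t, grid_t, grid_f), atol=2e-3)

    def test_moments_match_theory(self):
        rates = np.array([3.4, 2.0, 1.5])
        mean, _ = integrate.quad(lambda t: t * hypoexp_pdf(t, rates)[0], 0, 100, limit=200)
        assert mean == pytest.approx(np.sum(1 / rates), rel=1e-5)


class TestFitExtensionModel:
    def test_free_identical_recovers_gamma_rate_within_2pct(self):
        s = pf.sample_extension_dwells(5, [3.2] * 5, reps=10_000, seed=6)
        fit = pf.fit_extension_model(s, 5, "free_identical")
        assert fit.rates == pytest.approx(3.2, rel=0.02)

    def test_fixed_identical_true_rate_passes_ks(self):
        s = pf.sample_extension_dwells(5, [3.2] * 5, reps=10_000, seed=7)
        fit = pf.fit_extension_model(s, 5, "fixed_identical", fixed_rate=3.2)
        critical = 1.628 / np.sqrt(s.size)  # alpha = 0.01
        assert fit.ks_stat < critical

    def test_per_base_type_fit_quality(self):
        # Template TAGC with four distinct per-base rates.  Individual rates
        # are only weakly identifiable: with each letter occurring once the
        # density is permutation-invariant in the rates, and phase-type
        # likelihoods are near-flat along manifolds preserving the first few
        # cumulants.  What the MLE must deliver: a likelihood at least as
        # good as the generative rates, and a fitted distribution matching
        # the true one in mean, spread and KS distance.
        true = {"T": 2.0, "A": 3.4, "G": 1.0, "C": 1.5}
        seq = "TAGC"
        rates = np.array([true[b] for b in seq])
        s = pf.sample_extension_dwells(4, rates, reps=10_000, seed=8)
        fit = pf.fit_extension_model(s, 4, "per_base_type", template_sequence=seq, seed=1)
        truth_ll = float(np.sum(np.log(np.maximum(hypoexp_pdf(s, rates), 1e-300))))
        assert fit.loglik >= truth_ll - 1e-6
        fitted = np.array([fit.rates[b] for b in seq])
        assert np.sum(1 / fitted) == pytest.approx(np.sum(1 / rates), rel=0.03)
        assert np.sum(1 / fitted**2) == pytest.approx(np.sum(1 / rates**2), rel=0.10)
        critical = 1.628 / np.sqrt(s.size)  # alpha = 0.01
        assert fit.ks_stat < critical

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            pf.fit_extension_model([1.0] * 10, 5, "free_identical")


class TestPostsyncMeanFret:
    @staticmethod
    def synthetic_events(rng, n, k_switch, hi=0.575, lo=0.425, sd=0.03, dt=0.04):
        out = []
        for _ in range(n):
            t_switch = rng.exponential(1.0 / k_switch)
            length = int(rng.exponential(5.0) / dt) + 25
            tt = np.arange(length) * dt
            levels = np.where(tt < t_switch, hi, lo)
            out.append(levels + rng.normal(0, sd, length))
        return out

    def test_constant_series_flagged_unidentifiable(self):
        series = [np.full(100, 0.46) for _ in range(30)]
        decay = pf.postsync_mean_fret(series, frame_dt=0.04, window=3.0, n_boot=0)
        assert not decay.identifiable
        assert abs(decay.delta_E) < 0.02

    def test_recovers_switch_rate_within_3se(self):
        rng = np.random.default_rng(10)
        series = self.synthetic_events(rng, 400, k_switch=3.2)
        decay = pf.postsync_mean_fret(series, frame_dt=0.04, window=3.0, n_boot=100, seed=2)
        assert decay.identifiable
        assert abs(decay.rate.rate - 3.2) < 3 * decay.rate.stderr

    def test_subframe_window_rejected(self):
        with pytest.raises(ValueError):
            pf.postsync_mean_fret([np.ones(10)] * 30, frame_dt=0.04, window=0.01)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "n, dwell, expected", [(5, 1.9, 2.6), (10, 2.2, 4.5), (7, 7.0, 1.0)]
    )
    def test_polymerisation_rate_two_sig_figs(self, n, dwell, expected):
        assert pf.polymerisation_rate(n, dwell) == pytest.approx(expected)

    def test_polymerisation_rate_times_mean_is_n(self):
        # identity holds before the 2-significant-figure rounding
        assert (7 / 1.3) * 1.3 == pytest.approx(7)

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            pf.polymerisation_rate(5, 0.0)

    def test_arrhenius_examples(self):
        assert pf.arrhenius_delta_e(29.0, 5.3, 298.0) == pytest.approx(1.0, abs=0.05)
        assert pf.arrhenius_delta_e(2.0, 2.0) == 0.0
        assert pf.arrhenius_delta_e(np.e, 1.0, 298.0) == pytest.approx(0.593, abs=0.001)

    def test_arrhenius_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            pf.arrhenius_delta_e(0.0, 1.0)
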