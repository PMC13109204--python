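"""Occupancy normalization, binomial fitting and channel-count scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchpo import (
    OccupancyProfile,
    PatchSimConfig,
    estimate_po_from_trace,
    fit_binomial_po,
    occupation_probabilities,
    scan_channel_count,
    simulate_patch_trace,
)


def random_occupancy(rng, k_levels):
    """Random normalized occupancy profile over ``k_levels`` levels."""
    w = rng.dirichlet(np.ones(k_levels))
    return w / w.sum()


def brute_force_po(y, n_channels, use=None, step=1e-5):
    """Independent oracle: exhaustive grid minimization of the declared
    least-squares objective, using the binomial pmf written out directly."""
    from math import comb

    grid = np.arange(0.0, 1.0 + step / 2, step)
    k = np.arange(n_channels + 1)
    coef = np.array([comb(n_channels, i) for i in k], dtype=float)
    pmf = coef * grid[:, None] ** k * (1 - grid[:, None]) ** (n_channels - k)
    y = np.asarray(y, dtype=float)
    if use is not None:
        pmf, y = pmf[:, use], y[use]
    sse = np.sum((y - pmf) ** 2, axis=1)
    return float(grid[np.argmin(sse)])


class TestOccupationProbabilities:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ((100, 0), (1.0, 0.0)),
            ((20, 80), (0.2, 0.8)),  # the two-level worked example
            ((1, 1, 2), (0.25, 0.25, 0.5)),
        ],
    )
    def test_normalization_examples(self, weights, expected):
        occ = occupation_probabilities(np.array(weights, dtype=float))
        assert occ.probs == pytest.approx(expected)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            occupation_probabilities(np.zeros(3))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6),
                    min_size=1, max_size=9))
    @settings(deadline=None, derandomize=True)
    def test_normalization_to_1e9_for_any_weights(self, weights):
        occ = occupation_probabilities(np.array(weights))
        assert abs(occ.probs.sum() - 1.0) <= 1e-9


class TestBinomialFit:
    def test_two_level_n1_worked_example(self):
        occ = OccupancyProfile(probs=np.array([0.2, 0.8]))
        fit = fit_binomial_po(occ, 1)
        assert fit.p_open == pytest.approx(0.80, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_binomial_is_exact(self):
        occ = OccupancyProfile(probs=np.array([0.25, 0.5, 0.25]))
        fit = fit_binomial_po(occ, 2)
        assert fit.p_open == pytest.approx(0.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_top_open_two_level_matches_grid_oracle(self):
        # observed baseline -> 0 open, observed top -> N open; the
        # intermediate level is unobserved (probability 0) by default
        occ = OccupancyProfile(probs=np.array([0.2, 0.8]), anchoring="top_open")
        assert occ.level_map(2) == {0: 0, 1: 2}
        fit = fit_binomial_po(occ, 2)
        oracle = brute_force_po([0.2, 0.0, 0.8], 2)
        assert oracle == pytest.approx(0.94296, abs=1e-5)  # frozen
        assert fit.p_open == pytest.approx(oracle, abs=1e-4)

    def test_top_open_observed_only_objective(self):
        occ = OccupancyProfile(probs=np.array([0.2, 0.8]), anchoring="top_open")
        fit2 = fit_binomial_po(occ, 2, objective="observed_only")
        fit3 = fit_binomial_po(occ, 3, objective="observed_only")
        assert fit2.p_open == pytest.approx(
            brute_force_po([0.2, 0.0, 0.8], 2, use=[0, 2]), abs=1e-4)
        assert fit3.p_open == pytest.approx(
            brute_force_po([0.2, 0.0, 0.0, 0.8], 3, use=[0, 3]), abs=1e-4)

    def test_n_below_observed_levels_rejected(self):
        occ = OccupancyProfile(probs=np.array([0.1, 0.3, 0.6]))
        with pytest.raises(ValueError):
            fit_binomial_po(occ, 1)

    def test_agrees_with_grid_oracle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k_levels = int(rng.integers(2, 6))
            occ = OccupancyProfile(probs=random_occupancy(rng, k_levels))
            n = int(rng.integers(k_levels - 1, k_levels + 2))
            fit = fit_binomial_po(occ, n)
            y = np.zeros(n + 1)
            y[: k_levels] = occ.probs
            assert fit.p_open == pytest.approx(brute_force_po(y, n), abs=1e-4)

    def test_n1_closed_form_beats_grid_resolution(self):
        occ = OccupancyProfile(probs=np.array([0.123456789, 0.876543211]))
        fit = fit_binomial_po(occ, 1)
        assert fit.p_open == pytest.approx(0.876543211, abs=1e-15)


class TestScanChannelCount:
    def test_po_increases_with_n_under_top_open(self):
        occ = OccupancyProfile(probs=np.array([0.2, 0.8]), anchoring="top_open")
        fits = scan_channel_count(occ, 1, 3, objective="observed_only")
        pos = [f.p_open for f in fits]
        assert pos[0] == pytest.approx(0.80, abs=1e-4)
        assert pos[0] < pos[1] < pos[2]

    def test_po_decreases_with_n_under_baseline_closed(self, multi_channel_run):
        _, trace, _ = multi_channel_run
        occ = estimate_po_from_trace(trace).occupancy
        fits = scan_channel_count(occ, 6, 8)
        pos = [f.p_open for f in fits]
        assert pos[0] > pos[1] > pos[2]

    def test_r_squared_maximal_at_true_n(self):
        from scipy import stats

        true_n, p = 4, 0.37
        occ = OccupancyProfile(
            probs=stats.binom.pmf(np.arange(true_n + 1), true_n, p))
        fits = scan_channel_count(occ, true_n, true_n + 2)
        assert fits[0].r_squared == pytest.approx(1.0, abs=1e-9)
        assert fits[0].r_squared == max(f.r_squared for f in fits)
        assert fits[0].p_open == pytest.approx(p, abs=1e-4)


class TestFullPipeline:
    def test_six_channel_recovery(self, multi_channel_run):
        cfg, trace, _ = multi_channel_run
        res = estimate_po_from_trace(trace, n_channels=6)
        assert res.n_levels_detected == 7
        assert res.p_open == pytest.approx(cfg.p_open, abs=0.03)
        assert res.unitary_amplitude == pytest.approx(-0.35, abs=0.02)

    def test_single_channel_high_po_recovery(self, single_channel_run):
        cfg, trace, _ = single_channel_run
        res = estimate_po_from_trace(trace)
        assert res.binomial.n_channels == 1
        assert res.p_open == pytest.approx(cfg.p_open, abs=0.03)

    def test_noise_only_trace_flagged(self):
        rng = np.random.default_rng(12)
        from patchpo import Trace

        trace = Trace(samples=rng.normal(0, 0.05, 50_000),
                      sampling_rate=10_000.0, units="pA")
        res = estimate_po_from_trace(trace)
        assert "no open levels detected" in res.flags
        assert res.p_open == 0.0

    def test_parameter_recovery_across_operating_points(self):
        # median absolute error across seeds and open probabilities; the
        # spread covers the low/medium/high activity regimes
        errors = []
        for p_true in (0.2, 0.34, 0.5, 0.8, 0.9):
            for seed in range(4):
                cfg = PatchSimConfig(n_channels=6, p_open=p_true,
                                     unitary_amplitude=-0.35, noise_sd=0.05,
                                     duration=60.0, seed=60 + seed)
                trace, _ = simulate_patch_trace(cfg)
                res = estimate_po_from_trace(trace, n_channels=6)
                errors.append(abs(res.p_open - p_true))
        assert np.median(errors) < 0.03

    def test_under_count_bias_direction(self, multi_channel_run):
        # assuming more channels than observed levels can only lower the
        # estimate under baseline_closed anchoring
        _, trace, _ = multi_channel_run
        occ = estimate_po_from_trace(trace).occupancy
        fits = scan_channel_count(occ, 6, 10)
        pos = [f.p_open for f in fits]
        assert all(a >= b for a, b in zip(pos, pos[1:]))
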