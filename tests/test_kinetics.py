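"""Occupancies, dwell-time kinetics, transition densities and precision."""

import numpy as np
import pytest

from gietkit import (
    Trace,
    TraceSimSpec,
    axial_precision,
    occupancies,
    simulate_traces,
    states_to_heights,
    transition_density,
    transition_kinetics,
)
from gietkit.statemodel import StateModel


def chain_paths(rng, transmat, n_paths, n_frames):
    transmat = np.asarray(transmat)
    k = len(transmat)
    paths = []
    for _ in range(n_paths):
        s = np.empty(n_frames, dtype=int)
        s[0] = rng.integers(k)
        for t in range(1, n_frames):
            s[t] = rng.choice(k, p=transmat[s[t - 1]])
        paths.append(s)
    return paths


class TestOccupancies:
    def test_fractions_sum_to_one(self, rng):
        paths = chain_paths(rng, [[0.9, 0.1], [0.2, 0.8]], 20, 200)
        frac, sem = occupancies(paths, seed=0)
        assert frac.sum() == pytest.approx(1.0)
        assert np.all(sem >= 0)

    def test_matches_stationary_distribution(self, rng):
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        # stationary: pi = (2/3, 1/3)
        paths = chain_paths(rng, p, 100, 500)
        frac, sem = occupancies(paths, seed=0)
        assert frac[0] == pytest.approx(2 / 3, abs=3 * max(sem[0], 0.01))

    def test_single_state_data(self):
        frac, sem = occupancies([np.zeros(100, dtype=int)], seed=0)
        assert frac == pytest.approx([1.0])
        assert sem == pytest.approx([0.0])

    def test_bootstrap_seeded(self, rng):
        paths = chain_paths(rng, [[0.9, 0.1], [0.2, 0.8]], 10, 100)
        _, a = occupancies(paths, seed=5)
        _, b = occupancies(paths, seed=5)
        assert np.array_equal(a, b)


class TestTransitionKinetics:
    def test_two_state_rate_recovery(self, rng):
        """Dwell-time fits recover the generator rates of a CTMC."""
        k01, k10 = 1.0, 0.5  # 1/s
        dt = 0.032
        p = np.array([[1 - k01 * dt, k01 * dt], [k10 * dt, 1 - k10 * dt]])
        paths = chain_paths(rng, p, 500, 1500)
        kin = transition_kinetics(paths, dt)
        assert kin.exit_rate_per_s[0] == pytest.approx(k01, rel=0.15)
        assert kin.exit_rate_per_s[1] == pytest.approx(k10, rel=0.15)

    def test_pair_rates_sum_to_exit_rate(self, rng):
        p = np.array(
            [[0.94, 0.04, 0.02], [0.03, 0.94, 0.03], [0.02, 0.05, 0.93]]
        )
        paths = chain_paths(rng, p, 100, 300)
        kin = transition_kinetics(paths, 0.032)
        for i in range(3):
            if np.isfinite(kin.exit_rate_per_s[i]):
                assert np.nansum(kin.pair_rates_per_s[i]) == pytest.approx(
                    kin.exit_rate_per_s[i], rel=1e-9
                )

    def test_dwell_consistent_with_transition_matrix(self, rng):
        """Mean dwell from the fit matches dt / (1 - p_ii) on long chains."""
        p = np.array([[0.97, 0.03], [0.04, 0.96]])
        dt = 0.032
        paths = chain_paths(rng, p, 150, 2000)
        kin = transition_kinetics(paths, dt)
        for i in range(2):
            expected_rate = (1 - p[i, i]) / dt
            assert kin.exit_rate_per_s[i] == pytest.approx(expected_rate, rel=0.10)

    def test_no_transitions_yields_undefined_rates(self):
        kin = transition_kinetics([np.zeros(200, dtype=int)], 0.032, n_states=2)
        assert np.all(kin.transition_counts == 0)
        assert np.all(np.isnan(kin.exit_rate_per_s))
        assert np.all(np.isnan(kin.pair_rates_per_s))

    def test_rare_state_reports_count_not_rate(self, rng):
        # state 1 visited a handful of times only
        path = np.zeros(1000, dtype=int)
        path[100:103] = 1
        path[500:502] = 1
        kin = transition_kinetics([path], 0.032, n_states=2)
        assert np.isnan(kin.exit_rate_per_s[1])
        assert kin.n_complete_dwells[1] == 2

    def test_mle_option(self, rng):
        p = np.array([[0.96, 0.04], [0.05, 0.95]])
        paths = chain_paths(rng, p, 100, 300)
        a = transition_kinetics(paths, 0.032, method="survival")
        b = transition_kinetics(paths, 0.032, method="mle")
        assert b.exit_rate_per_s[0] == pytest.approx(a.exit_rate_per_s[0], rel=0.2)


def trace_from(y, tid=0):
    n = len(y)
    return Trace(tid, np.arange(n), np.zeros(n), np.zeros(n),
                 np.asarray(y, dtype=float))


class TestTransitionDensity:
    def test_two_state_alternator_concentrates_off_diagonal(self):
        path = np.tile(np.repeat([0, 1], 20), 5)
        y = np.where(path == 0, 100.0, 300.0)
        hist, xe, ye, pts = transition_density([path], [trace_from(y)], bins=4)
        assert len(pts) == 9
        assert set(map(tuple, np.unique(pts, axis=0))) == {
            (100.0, 300.0), (300.0, 100.0)
        }

    def test_no_transitions_empty(self):
        hist, _, _, pts = transition_density(
            [np.zeros(50, dtype=int)], [trace_from(np.full(50, 1.0))]
        )
        assert pts.shape == (0, 2)
        assert hist.sum() == 0

    def test_symmetric_chain_symmetric_histogram(self, rng):
        p = np.array([[0.9, 0.1], [0.1, 0.9]])
        paths = chain_paths(rng, p, 50, 400)
        traces = [trace_from(np.where(s == 0, 100.0, 300.0)) for s in paths]
        hist, _, _, pts = transition_density(paths, traces, bins=2,
                                             range_=((0, 400), (0, 400)))
        up = hist[0, 1]
        down = hist[1, 0]
        assert abs(up - down) / (up + down) < 0.1


class TestStatesToHeights:
    def test_reference_ratios_invert_to_reported_heights(self, dy647_curve):
        model = StateModel(
            means=np.array([250.0, 410.0, 690.0]),
            sds=np.array([60.0, 80.0, 130.0]),
            transition_matrix=np.full((3, 3), 1 / 3),
            initial_distribution=np.full(3, 1 / 3),
        )
        hts = states_to_heights(model, 1000.0, dy647_curve)
        assert hts[0].h_nm == pytest.approx(4.7, abs=0.3)
        assert hts[1].h_nm == pytest.approx(6.8, abs=0.3)
        assert hts[2].h_nm == pytest.approx(11.2, abs=0.3)

    def test_exact_round_trip_with_zero_sd(self, dy647_curve):
        d0 = 9.0
        r = dy647_curve(d0)
        model = StateModel(
            means=np.array([r * 500.0]),
            sds=np.array([1e-9]),
            transition_matrix=np.array([[1.0]]),
            initial_distribution=np.array([1.0]),
        )
        hts = states_to_heights(model, 500.0, dy647_curve)
        assert hts[0].d_nm == pytest.approx(d0, abs=0.01)

    def test_requires_positive_reference(self, dy647_curve):
        model = StateModel(
            means=np.array([100.0]),
            sds=np.array([1.0]),
            transition_matrix=np.array([[1.0]]),
            initial_distribution=np.array([1.0]),
        )
        with pytest.raises(ValueError):
            states_to_heights(model, 0.0, dy647_curve)


class TestAxialPrecision:
    def test_reference_propagation(self):
        """7.5% per-intensity noise propagates to 10.6% on the ratio."""
        rel = 0.075
        n = 1000
        y = 500.0 * np.ones(n)
        y[::2] = 500.0 * (1 + rel)
        y[1::2] = 500.0 * (1 - rel)
        est = axial_precision([trace_from(y)])
        assert est.pooled_relative_error == pytest.approx(rel, rel=1e-6)
        assert est.ratio_relative_error == pytest.approx(0.106, abs=0.001)

    def test_constant_trace_zero_error(self):
        est = axial_precision([trace_from(np.full(100, 123.0))])
        assert est.pooled_relative_error == 0.0
        assert est.ratio_relative_error == 0.0

    def test_gaussian_cv_recovered(self, rng):
        traces = [
            trace_from(400.0 * (1 + 0.05 * rng.standard_normal(2000)), tid=i)
            for i in range(20)
        ]
        est = axial_precision(traces)
        assert est.pooled_relative_error == pytest.approx(0.05, rel=0.05)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            axial_precision([trace_from(np.zeros(10))])


class TestEndToEndSimulated:
    def test_simulated_state_means_match_design(self, dy647_curve):
        spec = TraceSimSpec(
            heights_nm=(4.7, 6.8, 11.2),
            curve=dy647_curve,
            rate_matrix_per_s=np.zeros((3, 3)),
            n_traces=30,
            n_frames=300,
            noise_cv=0.075,
        )
        traces, paths = simulate_traces(spec, seed=11)
        design = spec.state_means()
        # frozen chain: each trace stays in its initial state
        for tr, p in zip(traces, paths):
            assert len(np.unique(p)) == 1
            assert np.mean(tr.intensity) == pytest.approx(
                design[p[0]], rel=4 * 0.075 / np.sqrt(len(tr))
            )
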