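"""Monte-Carlo simulator: photon trains, dead-time thinning, superposition."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from qbump import (
    ModelParams,
    bump_waveform,
    exact_mechanistic_qe,
    run_experiment,
    sample_photon_train,
    superpose,
    transduce,
)
from qbump.simulator import _transduce_no_loss, intensity_response


def rng_of(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


class TestPhotonTrain:
    def test_zero_rate_gives_empty_train(self):
        train = sample_photon_train(0.0, 1000.0, rng_of(0))
        assert train.n_photons == 0

    def test_count_mean_matches_poisson(self):
        lam, duration, reps = 0.5, 1000.0, 300
        rng = rng_of(11)
        counts = [sample_photon_train(lam, duration, rng).n_photons for _ in range(reps)]
        se = np.sqrt(lam * duration / reps)
        assert abs(np.mean(counts) - lam * duration) < 4 * se

    def test_gaps_are_exponential(self):
        # goodness-of-fit on 1e5 inter-arrival gaps at alpha = 0.01
        lam = 0.2
        train = sample_photon_train(lam, 1e5 / lam, rng_of(5))
        gaps = np.diff(train.arrival_times)
        assert gaps.size > 90_000
        result = stats.kstest(gaps, "expon", args=(0.0, 1.0 / lam))
        assert result.pvalue > 0.01

    def test_times_within_window_and_increasing(self):
        train = sample_photon_train(0.05, 5000.0, rng_of(3))
        assert np.all(np.diff(train.arrival_times) > 0)
        assert train.arrival_times[0] >= 0
        assert train.arrival_times[-1] <= 5000.0


class TestTransduce:
    def test_single_photon_yields_single_bump(self, default_params):
        train = dataclasses.replace(
            sample_photon_train(0.0, 100.0, rng_of(0)), arrival_times=np.array([50.0])
        )
        qb = transduce(train, default_params, rng_of(1))
        assert qb.n_bumps == 1
        assert qb.lost_photon_count == 0
        assert qb.bump_onsets[0] == pytest.approx(50.0 + qb.latencies[0])

    def test_second_photon_in_blocked_window_is_lost(self, default_params):
        train = dataclasses.replace(
            sample_photon_train(0.0, 100.0, rng_of(0)),
            arrival_times=np.array([50.0, 51.0]),
        )
        qb = transduce(train, default_params, rng_of(1))
        assert qb.n_bumps == 1
        assert qb.lost_photon_count == 1

    def test_photon_conservation(self, default_params):
        train = sample_photon_train(0.05, 100_000.0, rng_of(7))
        qb = transduce(train, default_params, rng_of(8))
        assert qb.n_bumps + qb.lost_photon_count == train.n_photons

    def test_minimum_separation_of_accepted_photons(self, default_params):
        train = sample_photon_train(0.1, 100_000.0, rng_of(9))
        qb = transduce(train, default_params, rng_of(10))
        acc, lat, ref = qb.accepted_photon_times, qb.latencies, qb.refractories
        blocked = acc[:-1] + lat[:-1] + default_params.bump_duration + ref[:-1]
        assert np.all(acc[1:] >= blocked)
        assert np.allclose(qb.bump_onsets, acc + lat)

    def test_accepted_fraction_matches_mechanistic_gain(self, default_params):
        # long run at lambda = 0.1/ms against 1/(1 + lambda E(S))
        lam = 0.1
        n_villi, duration = 200, 20_000.0
        burn = default_params.mean_minimum_interval() + 5 * default_params.mean_latency()
        per_b, per_p = [], []
        master = np.random.SeedSequence(42).spawn(n_villi)
        for child in master:
            rng = np.random.default_rng(child)
            train = sample_photon_train(lam, duration, rng)
            qb = transduce(train, default_params, rng)
            per_b.append(np.sum(qb.accepted_photon_times >= burn))
            per_p.append(np.sum(train.arrival_times >= burn))
        per_b, per_p = np.array(per_b), np.array(per_p)
        qe = per_b.sum() / per_p.sum()
        se = np.sqrt(np.sum((per_b - qe * per_p) ** 2)) / per_p.sum()
        oracle = exact_mechanistic_qe(default_params, lam)
        assert abs(qe - oracle) < 3 * max(se, 1e-12)


class TestBumpWaveform:
    def test_unit_peak_and_timing(self, default_params):
        dt = 0.1
        w = bump_waveform(default_params, dt)
        assert w.max() == 1.0
        assert abs(np.argmax(w) * dt - 8.0) <= dt
        assert w[0] == 0.0

    def test_truncated_at_small_amplitude(self, default_params):
        w = bump_waveform(default_params, 0.1)
        assert w[-1] >= 1e-4
        assert w[-1] < 1e-3


class TestSuperpose:
    def test_no_bumps_gives_zero_trace(self, default_params):
        trace = superpose([], default_params, dt=0.5, duration=100.0)
        assert np.all(trace.current == 0)

    def test_single_bump_peaks_at_amplitude(self, default_params):
        params = dataclasses.replace(default_params, bump_amplitude=2.5)
        train = sample_photon_train(0.0, 200.0, rng_of(0))
        qb = transduce(
            dataclasses.replace(train, arrival_times=np.array([40.0])), params, rng_of(2)
        )
        trace = superpose([qb], params, dt=0.5, duration=200.0)
        assert trace.current.max() == pytest.approx(2.5)
        assert np.all(trace.current >= 0)

    def test_linearity_across_microvilli(self, default_params):
        rng = rng_of(21)
        qbs = []
        for mv in range(2):
            train = sample_photon_train(0.02, 5000.0, rng, mv)
            qbs.append(transduce(train, default_params, rng))
        both = superpose(qbs, default_params, dt=0.5, duration=5000.0)
        parts = [superpose([qb], default_params, dt=0.5, duration=5000.0) for qb in qbs]
        assert np.array_equal(both.current, parts[0].current + parts[1].current)

    def test_campbell_theorem_steady_state_mean(self, default_params):
        # shot-noise mean = N * bump rate * h * integral of B(t) dt
        lam, n_villi, duration, dt = 0.05, 100, 20_000.0, 0.5
        qbs, per_counts = [], []
        for child in np.random.SeedSequence(33).spawn(n_villi):
            rng = np.random.default_rng(child)
            train = sample_photon_train(lam, duration, rng)
            qb = transduce(train, default_params, rng)
            qbs.append(qb)
            per_counts.append(qb.n_bumps)
        trace = superpose(qbs, default_params, dt, duration)
        wave = bump_waveform(default_params, dt)
        area = np.trapezoid(wave, dx=dt)
        rate = 1.0 / (default_params.mean_minimum_interval() + 1.0 / lam)
        expected = n_villi * rate * default_params.bump_amplitude * area
        # discard startup and waveform tail edges
        mask = (trace.times > 500.0) & (trace.times < duration - 100.0)
        measured = trace.current[mask].mean()
        se = expected * np.std(per_counts) / np.mean(per_counts) / np.sqrt(n_villi)
        assert abs(measured - expected) < 3 * se


class TestRunExperiment:
    def test_same_seed_is_bit_identical(self, default_params):
        params = dataclasses.replace(default_params, n_microvilli=50)
        a = run_experiment(params, 3e5, 20_000.0, seed=5, with_trace=True)
        b = run_experiment(params, 3e5, 20_000.0, seed=5, with_trace=True)
        assert a.n_photons == b.n_photons
        assert a.n_bumps == b.n_bumps
        assert np.array_equal(a.interbump_intervals, b.interbump_intervals)
        assert np.array_equal(a.trace.current, b.trace.current)

    def test_different_seed_differs(self, default_params):
        params = dataclasses.replace(default_params, n_microvilli=50)
        a = run_experiment(params, 3e5, 20_000.0, seed=5)
        b = run_experiment(params, 3e5, 20_000.0, seed=6)
        assert a.n_photons != b.n_photons or a.n_bumps != b.n_bumps

    def test_short_duration_records_warning(self, default_params):
        params = dataclasses.replace(default_params, n_microvilli=20)
        with pytest.warns(UserWarning):
            res = run_experiment(params, 3e5, 2000.0, seed=1)
        assert res.warnings

    def test_empirical_qe_matches_oracle(self, default_params):
        params = dataclasses.replace(default_params, n_microvilli=500)
        lam = 0.01
        res = run_experiment(params, lam * params.n_microvilli * 1000.0, 60_000.0, seed=17)
        oracle = exact_mechanistic_qe(params, lam)
        assert abs(res.empirical_qe - oracle) < 3 * res.qe_standard_error()

    def test_interval_histogram_concentrates_above_blocked_window(self, default_params):
        # the exact mechanism forbids intervals shorter than D + R (+ latency
        # difference), so unlike the two-branch mixture approximation the
        # simulated histogram carries no secondary mode at small intervals;
        # its bulk sits at the refractory-dominated scale
        params = dataclasses.replace(default_params, n_microvilli=200)
        res = run_experiment(params, 0.01 * 200 * 1000.0, 60_000.0, seed=23)
        iv = res.interbump_intervals
        assert iv.min() > params.bump_duration
        assert np.mean(iv < 40.0) < 0.02
        counts, edges = np.histogram(iv, bins=np.arange(0.0, 600.0, 20.0))
        mode_center = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert 80.0 < mode_center < 350.0
        assert iv.mean() == pytest.approx(
            params.mean_minimum_interval() + 1.0 / 0.01, rel=0.05
        )


class TestIntensityResponse:
    def test_no_loss_transduces_every_photon(self, default_params):
        params = dataclasses.replace(default_params, n_microvilli=100)
        tab = intensity_response(params, [1e4], "no_loss", 5000.0, seed=3)
        assert tab.empirical_qe.iloc[0] == 1.0

    def test_mode_ordering_at_bright_light(self, default_params):
        params = dataclasses.replace(default_params, n_microvilli=200)
        means = {}
        for mode in ("no_loss", "bump_blocking_only", "full"):
            tab = intensity_response(params, [2e4], mode, 5000.0, seed=9)
            means[mode] = tab.mean_lic_au.iloc[0]
        assert means["full"] < means["bump_blocking_only"] < means["no_loss"]

    def test_no_loss_latency_sampling_preserves_count(self, default_params):
        train = sample_photon_train(0.05, 10_000.0, rng_of(4))
        qb = _transduce_no_loss(train, default_params, rng_of(5))
        assert qb.n_bumps == train.n_photons
        assert qb.lost_photon_count == 0
        assert np.all(np.diff(qb.bump_onsets) >= 0)
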