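"""Spike-train theta rhythmicity, LFP theta cycles, phase locking,
cycle skipping and cluster quality."""

import numpy as np
import pytest
from scipy.special import i0, i1

from parahd._circular import circ_dist, resultant
from parahd.core import LFPTrace, SpikeTrain
from parahd.rhythmicity import (AutocorrHist, RateSpectrum, detect_theta,
                                fit_theta_index_mixture, isolation_distance,
                                lfp_phase, rate_power_spectrum,
                                refractory_ratio, spike_phase_locking,
                                spike_time_autocorrelation,
                                theta_index, theta_skipping_index)
from parahd.synthetic import HDCellParams, make_schedule, simulate_hd_cell


def _poisson_train(rate, duration, seed):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


def _modulated_train(rate, depth, freq, duration, seed):
    rng = np.random.default_rng(seed)
    lam_max = rate * (1 + depth)
    n = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0, duration, n))
    lam = rate * (1 + depth * np.cos(2 * np.pi * freq * cand))
    return cand[rng.uniform(0, lam_max, n) < lam]


class TestRateSpectrum:
    def test_modulated_train_peaks_at_8hz(self):
        spikes = _modulated_train(20.0, 0.8, 8.0, 300.0, seed=1)
        spec = rate_power_spectrum(spikes, (0.0, 300.0))
        band = (spec.freq > 4) & (spec.freq < 14)
        peak_f = spec.freq[band][np.argmax(spec.power[band])]
        assert 7.5 <= peak_f <= 8.5

    def test_two_modulations_both_visible(self):
        rng = np.random.default_rng(2)
        rate, dur = 20.0, 300.0
        lam_max = rate * (1 + 0.8) * (1 + 0.4)
        n = rng.poisson(lam_max * dur)
        cand = np.sort(rng.uniform(0, dur, n))
        lam = rate * (1 + 0.8 * np.cos(2 * np.pi * 8 * cand)) \
            * (1 + 0.4 * np.cos(2 * np.pi * 16 * cand))
        spikes = cand[rng.uniform(0, lam_max, n) < lam]
        spec = rate_power_spectrum(spikes, (0.0, dur))

        def band_peak(lo, hi):
            m = (spec.freq >= lo) & (spec.freq <= hi)
            return spec.power[m].max()

        noise = np.median(spec.power[(spec.freq > 20) & (spec.freq < 40)])
        assert band_peak(7.5, 8.5) > 3 * noise
        assert band_peak(15.5, 16.5) > 3 * noise
        assert band_peak(7.5, 8.5) > band_peak(15.5, 16.5)

    def test_too_few_spikes_flagged(self):
        assert rate_power_spectrum(np.arange(50) * 1.0, (0.0, 100.0)) is None

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            rate_power_spectrum(np.arange(200) * 0.1, (0.0, 20.0))


class TestThetaIndex:
    def _spec(self, theta, base):
        return RateSpectrum(np.array([4.0, 8.0, 12.0]),
                            np.array([base, theta, base]), theta, base, 1000)

    def test_equal_bands_zero(self):
        assert theta_index(self._spec(2.0, 2.0)) == 0.0

    def test_zero_baseline_one(self):
        assert theta_index(self._spec(2.0, 0.0)) == 1.0

    def test_antisymmetric_under_band_swap(self):
        a = theta_index(self._spec(3.0, 1.0))
        b = theta_index(self._spec(1.0, 3.0))
        assert a == pytest.approx(-b)
        assert -1.0 <= a <= 1.0

    def test_flat_poisson_near_zero(self):
        vals = [theta_index(rate_power_spectrum(
            _poisson_train(20.0, 300.0, seed=s), (0.0, 300.0)))
            for s in range(5)]
        assert abs(np.mean(vals)) < 0.05

    def test_monotone_in_modulation_depth(self):
        vals = []
        for depth in (0.0, 0.3, 0.6, 0.9):
            per_seed = [theta_index(rate_power_spectrum(
                _modulated_train(20.0, depth, 8.0, 300.0, seed=10 + s),
                (0.0, 300.0))) for s in range(3)]
            vals.append(np.mean(per_seed))
        assert np.all(np.diff(vals) > 0)


class TestMixture:
    def test_single_gaussian_selects_k1(self):
        rng = np.random.default_rng(3)
        fit = fit_theta_index_mixture(rng.normal(0.2, 0.02, 100), seed=1)
        assert fit.k == 1

    def test_two_component_recovery(self):
        rng = np.random.default_rng(4)
        lo = rng.normal(0.02, 0.01, 34)
        hi = rng.normal(0.30, 0.10, 59)
        fit = fit_theta_index_mixture(np.concatenate([lo, hi]), seed=1)
        assert fit.k == 2
        assert abs(fit.means[0] - 0.02) < 0.01   # within one truth sd
        assert abs(fit.means[1] - 0.30) < 0.10
        assert 0.05 < fit.threshold < 0.15
        truth = np.r_[np.zeros(34), np.ones(59)]
        assert np.mean(fit.labels == truth) >= 0.95

    def test_too_few_indices_rejected(self):
        with pytest.raises(ValueError):
            fit_theta_index_mixture(np.zeros(5))


class TestDetectTheta:
    def _sine_lfp(self, freq, duration=20.0, fs=1000.0, noise=0.0, seed=0):
        t = np.arange(int(duration * fs)) / fs
        x = np.cos(2 * np.pi * freq * t)
        if noise:
            x = x + noise * np.random.default_rng(seed).normal(0, 1, t.size)
        return LFPTrace("t1", fs, 100 * x)

    def test_pure_8hz_full_epoch_125ms_cycles(self):
        cycles = detect_theta(self._sine_lfp(8.0))
        covered = np.sum(cycles.epochs[:, 1] - cycles.epochs[:, 0])
        assert covered >= 0.95 * 20.0
        lens = np.diff(cycles.boundaries)
        lens = lens[lens < 0.3]
        assert np.median(lens) == pytest.approx(0.125, rel=0.01)

    def test_pure_3hz_no_theta(self):
        cycles = detect_theta(self._sine_lfp(3.0))
        assert cycles.epochs.shape[0] == 0

    def test_noisy_8hz_cycle_count(self):
        # SNR 2 in amplitude-ish terms: noise sd = 0.5 x signal amplitude
        cycles = detect_theta(self._sine_lfp(8.0, duration=60.0, noise=0.35,
                                             seed=5))
        covered = np.sum(cycles.epochs[:, 1] - cycles.epochs[:, 0])
        assert cycles.cycles.shape[0] == pytest.approx(covered * 8.0, rel=0.02)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_theta(LFPTrace("t1", 1000.0, np.zeros(500)))


class TestPhaseLocking:
    @pytest.fixture()
    def cycles(self):
        return detect_theta(LFPTrace(
            "t1", 1000.0,
            100 * np.cos(2 * np.pi * 8.0 * np.arange(60_000) / 1000.0)))

    def test_cosine_trough_maps_to_90_degrees(self, cycles):
        # spikes exactly at the LFP troughs of a cosine-referenced cycle
        trough_times = (np.arange(40) + 0.5) / 8.0 + 1.0
        pl = spike_phase_locking(SpikeTrain("c", "t1", trough_times), cycles)
        assert circ_dist(pl.preferred_phase, 90.0) < 5.0
        assert pl.mvl > 0.99

    def test_spikes_at_boundaries_phase_zero(self, cycles):
        b = cycles.boundaries[10:50]
        pl = spike_phase_locking(SpikeTrain("c", "t1", b + 1e-6), cycles)
        assert pl.mvl > 0.999
        assert min(pl.preferred_phase, 360 - pl.preferred_phase) < 2.0

    def test_uniform_phases_not_locked(self, cycles):
        n_nonsig = 0
        for seed in range(10):
            rng = np.random.default_rng(40 + seed)
            spikes = np.sort(rng.uniform(2.0, 58.0, 1000))
            pl = spike_phase_locking(SpikeTrain("c", "t1", spikes), cycles)
            assert pl.mvl < 0.1
            n_nonsig += pl.rayleigh_p > 0.05
        assert n_nonsig >= 9

    def test_von_mises_phases_match_bessel_ratio(self, cycles):
        # spikes placed at von Mises phases (kappa=1) around 180 deg
        rng = np.random.default_rng(6)
        kappa, mu = 1.0, 180.0
        phases = np.rad2deg(rng.vonmises(np.deg2rad(mu), kappa, 4000)) % 360
        cyc = cycles.cycles
        pick = rng.integers(0, cyc.shape[0], phases.size)
        times = np.sort(cyc[pick, 0]
                        + (phases / 360.0) * (cyc[pick, 1] - cyc[pick, 0]))
        pl = spike_phase_locking(SpikeTrain("c", "t1", times), cycles)
        assert pl.mvl == pytest.approx(i1(kappa) / i0(kappa), abs=0.03)
        assert circ_dist(pl.preferred_phase, mu) < 10.0

    def test_rayleigh_matches_monte_carlo_null(self, cycles):
        # p-value approximation vs brute-force uniform-null simulation, n=50
        rng = np.random.default_rng(7)
        sample = rng.uniform(0, 360, 50)
        r_obs, _ = resultant(sample)
        null_r = np.array([resultant(rng.uniform(0, 360, 50))[0]
                           for _ in range(2000)])
        p_mc = np.mean(null_r >= r_obs)
        from parahd._circular import rayleigh_test
        _, p = rayleigh_test(sample)
        assert p == pytest.approx(p_mc, abs=3 * np.sqrt(p_mc * (1 - p_mc) / 2000) + 0.01)


class TestSpikeAutocorrelation:
    def test_two_spike_train_single_count(self):
        ac = spike_time_autocorrelation(np.array([1.0, 1.010]), 300.0, 2.0)
        assert ac.counts.sum() == 1
        assert ac.counts[np.argmin(np.abs(ac.lags - 11.0))] == 1

    def test_poisson_flat_at_rate_squared(self):
        rate, dur = 30.0, 200.0
        spikes = _poisson_train(rate, dur, seed=8)
        ac = spike_time_autocorrelation(spikes, 300.0, 2.0)
        expected = rate * rate * dur * 0.002   # pairs per 2-ms bin
        assert np.mean(ac.counts) == pytest.approx(expected, rel=0.05)
        assert np.std(ac.counts) < 0.2 * expected

    def test_theta_locked_maxima_near_125_and_250(self):
        spikes = _modulated_train(20.0, 0.9, 8.0, 600.0, seed=9)
        ac = spike_time_autocorrelation(spikes, 300.0, 2.0)
        sm = np.convolve(ac.counts, np.ones(5) / 5, mode="same")
        m1 = ac.lags[(ac.lags > 90) & (ac.lags < 160)][
            np.argmax(sm[(ac.lags > 90) & (ac.lags < 160)])]
        m2 = ac.lags[(ac.lags > 210) & (ac.lags < 290)][
            np.argmax(sm[(ac.lags > 210) & (ac.lags < 290)])]
        assert abs(m1 - 125) < 15 and abs(m2 - 250) < 20


class TestSkippingIndex:
    def _hist(self, p1, p2):
        lags = np.arange(1.0, 300.0, 2.0)
        counts = np.zeros(lags.size)
        counts[np.argmin(np.abs(lags - 125))] = p1
        counts[np.argmin(np.abs(lags - 250))] = p2
        return AutocorrHist(lags, counts, 2.0, 300.0)

    def test_formula(self):
        assert theta_skipping_index(self._hist(10, 10))[0] == 0.0
        assert theta_skipping_index(self._hist(0, 5)) == (1.0, True)
        idx, flag = theta_skipping_index(self._hist(20, 10))
        assert idx == pytest.approx(-0.5) and not flag

    def test_empty_undefined(self):
        idx, flag = theta_skipping_index(self._hist(0, 0))
        assert np.isnan(idx) and not flag


class TestClusterQuality:
    def test_clean_refractory_zero(self):
        lags = np.arange(0.25, 25.0, 0.5)
        counts = np.where(lags > 3.0, 50.0, 0.0)
        ratio, discard = refractory_ratio(AutocorrHist(lags, counts, 0.5, 25.0))
        assert ratio == 0.0 and not discard

    def test_flat_autocorr_discarded(self):
        lags = np.arange(0.25, 25.0, 0.5)
        counts = np.full(lags.size, 40.0)
        ratio, discard = refractory_ratio(AutocorrHist(lags, counts, 0.5, 25.0))
        assert ratio == pytest.approx(1.0) and discard

    def test_dead_time_poisson_kept(self):
        kept = 0
        for seed in range(10):
            spikes = _poisson_train(25.0, 300.0, seed=50 + seed)
            isi_ok = np.concatenate([[True], np.diff(spikes) >= 0.003])
            spikes = spikes[isi_ok]
            ac = spike_time_autocorrelation(spikes, 25.0, 0.5)
            ratio, discard = refractory_ratio(ac)
            kept += not discard
        assert kept >= 9

    def test_isolation_distance_orders_separation(self):
        rng = np.random.default_rng(10)
        cluster = rng.normal(0, 1, size=(200, 4))
        near = rng.normal(1.0, 1, size=(400, 4))
        far = rng.normal(6.0, 1, size=(400, 4))
        assert isolation_distance(cluster, far) > \
            isolation_distance(cluster, near) > 0
        assert isolation_distance(cluster, near[:100]) != \
            isolation_distance(cluster, near)  # depends on n-th neighbor


class TestThetaCellsEndToEnd:
    def test_simulated_depths_split_by_index(self, traj_20min, lfp_20min):
        _, phase = lfp_20min
        sched = make_schedule(10, 120.0)
        idx = {}
        for name, depth in (("nr", 0.0), ("tr", 0.8)):
            cell = simulate_hd_cell(
                HDCellParams(kappa=0.0, peak_vp1=15.0, peak_vp2=15.0,
                             baseline=15.0, theta_depth=depth),
                traj_20min, phase, sched, seed=60 + (depth > 0))
            spec = rate_power_spectrum(cell, (0.0, 1200.0))
            idx[name] = theta_index(spec)
        assert idx["nr"] < 0.07 < idx["tr"]

    def test_lfp_phase_interpolation_bounds(self, lfp_20min):
        lfp, _ = lfp_20min
        cycles = detect_theta(lfp)
        ph = lfp_phase(cycles, np.linspace(10, 1190, 1000))
        ok = np.isfinite(ph)
        assert ok.mean() > 0.9
        assert np.all((ph[ok] >= 0) & (ph[ok] <= 360))
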