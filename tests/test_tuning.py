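"""HD tuning curves, rate maps, distributive ratio, egocentric bearing,
bidirectionality and map correlations."""

import numpy as np
import pytest
from scipy.special import i0, i1

from parahd._circular import circ_dist, wrap360
from parahd.core import SpikeTrain, Trajectory
from parahd.synthetic import HDCellParams, make_schedule, simulate_hd_cell
from parahd import tuning
from parahd.tuning import (HD_BIN_CENTERS, BDResult, HDTuningCurve, RateMap,
                           bd_scores, curve_from_histograms, dr_formula,
                           distributive_ratio, egocentric_bearing_tuning,
                           firing_rate_map, hd_score_and_preferred,
                           hd_tuning_curve, lagged_pearson, map_similarity,
                           spatial_crosscorrelation)


def _curve(rate):
    rate = np.asarray(rate, dtype=float)
    return HDTuningCurve(HD_BIN_CENTERS.copy(), rate, np.ones(36))


def _untuned_cell(traj, rate_hz, seed):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * (traj.t[-1] - traj.t[0]))
    return SpikeTrain("c", "t1", np.sort(rng.uniform(traj.t[0], traj.t[-1], n)))


class TestHDScore:
    def test_flat_curve_scores_zero(self):
        score, pref = hd_score_and_preferred(_curve(np.full(36, 4.0)))
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_is_perfectly_tuned(self):
        rate = np.zeros(36)
        rate[9] = 10.0  # bin center 95 deg
        score, pref = hd_score_and_preferred(_curve(rate))
        assert score == pytest.approx(1.0)
        assert pref == pytest.approx(95.0)

    def test_all_zero_curve_undefined_preferred(self):
        score, pref = hd_score_and_preferred(_curve(np.zeros(36)))
        assert score == 0.0 and np.isnan(pref)

    def test_ideal_von_mises_matches_bessel_ratio(self):
        # resultant of exp(kappa*cos) equals I1(kappa)/I0(kappa)
        kappa = 2.0
        rate = np.exp(kappa * np.cos(np.deg2rad(HD_BIN_CENTERS - 90.0)))
        score, pref = hd_score_and_preferred(_curve(rate))
        assert score == pytest.approx(i1(kappa) / i0(kappa), rel=0.01)
        assert circ_dist(pref, 90.0) < 1e-6

    def test_resultant_bounded_for_random_curves(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            score, _ = hd_score_and_preferred(_curve(rng.uniform(0, 30, 36)))
            assert 0.0 <= score <= 1.0


class TestHDTuningCurve:
    def test_untuned_cell_flat_at_mean_rate(self, traj_20min):
        cell = _untuned_cell(traj_20min, 8.0, seed=1)
        curve = hd_tuning_curve(cell, traj_20min)
        assert np.nanmax(np.abs(curve.rate - 8.0)) < 1.5
        score, _ = hd_score_and_preferred(curve)
        assert score < 0.05

    def test_zero_occupancy_bin_undefined(self):
        occ = np.ones(36)
        occ[0:12] = 0.0  # arc wider than the kernel support (radius 4 bins)
        cnt = np.ones(36)
        curve = curve_from_histograms(occ, cnt)
        assert np.isnan(curve.rate[5])
        assert np.isfinite(curve.rate[20])

    def test_von_mises_cell_matches_generative_rate(self, traj_20min,
                                                    schedule_40):
        params = HDCellParams(pref_vp1=200.0, pref_vp2=200.0, kappa=2.0,
                              peak_vp1=20.0, peak_vp2=20.0)
        cell = simulate_hd_cell(params, traj_20min, None,
                                make_schedule(10, 120.0), seed=3)
        curve = hd_tuning_curve(cell, traj_20min)
        lam = (params.baseline + (params.peak_vp1 - params.baseline)
               * np.exp(params.kappa
                        * (np.cos(np.deg2rad(HD_BIN_CENTERS - 200.0)) - 1.0)))
        # smoothing flattens the peak slightly; compare within 15% + 0.5 Hz
        assert np.all(np.abs(curve.rate - lam) < 0.15 * lam + 0.6)

    def test_preferred_direction_recovery_within_5_deg(self, traj_20min):
        sched = make_schedule(10, 120.0)
        for seed in range(5):
            true_pref = 72.0 * seed + 13.0
            params = HDCellParams(pref_vp1=true_pref, pref_vp2=true_pref,
                                  kappa=2.0, peak_vp1=20.0, peak_vp2=20.0)
            cell = simulate_hd_cell(params, traj_20min, None, sched,
                                    seed=50 + seed)
            assert cell.n > 2000
            _, pref = hd_score_and_preferred(hd_tuning_curve(cell, traj_20min))
            assert circ_dist(pref, true_pref) <= 5.0


class TestRateMap:
    def test_no_spikes_zero_map(self, traj_20min):
        cell = SpikeTrain("c", "t1", np.array([]))
        m = firing_rate_map(cell, traj_20min)
        assert np.nanmax(m.rate) == 0.0

    def test_occupancy_conservation(self, traj_20min):
        from parahd.core import compute_speed
        cell = _untuned_cell(traj_20min, 3.0, seed=2)
        m = firing_rate_map(cell, traj_20min)
        speed = compute_speed(traj_20min)
        expected = np.sum(np.isfinite(speed) & (speed > 3.0)) * traj_20min.dt
        assert m.occupancy_s.sum() == pytest.approx(expected, rel=1e-6)
        assert m.occupancy_p.sum() == pytest.approx(1.0)

    def test_place_field_centroid_recovered(self, traj_20min):
        params = HDCellParams(kappa=0.0, peak_vp1=2.0, peak_vp2=2.0,
                              baseline=2.0, place_field=(35.0, 35.0, 8.0, 10.0))
        cell = simulate_hd_cell(params, traj_20min, None,
                                make_schedule(10, 120.0), seed=4)
        m = firing_rate_map(cell, traj_20min)
        rate = np.nan_to_num(m.rate)
        xs = (np.arange(35) + 0.5) * 2.0
        w = rate - rate.min()
        cx = np.sum(w.sum(axis=1) * xs) / w.sum()
        cy = np.sum(w.sum(axis=0) * xs) / w.sum()
        # rate-weighted centroid of the map within 2 cm of the field center
        assert abs(cx - 35.0) < 2.0 and abs(cy - 35.0) < 2.0


class TestDistributiveRatio:
    def test_identical_curves_zero(self):
        assert dr_formula(np.full(36, 3.0), np.full(36, 3.0)) == 0.0

    def test_single_bin_closed_form(self):
        r_obs = np.ones(36)
        r_pred = np.ones(36)
        r_obs[0] = 3.0  # ln((1+3)/(1+1)) = ln 2 in one of 36 bins
        assert dr_formula(r_obs, r_pred) == pytest.approx(np.log(2) / 36)

    def test_dr_separates_place_from_hd_cells(self, traj_20min):
        sched = make_schedule(10, 120.0)
        place = simulate_hd_cell(
            HDCellParams(kappa=0.0, peak_vp1=1.0, peak_vp2=1.0, baseline=1.0,
                         place_field=(20.0, 50.0, 8.0, 15.0)),
            traj_20min, None, sched, seed=5)
        hd = simulate_hd_cell(
            HDCellParams(pref_vp1=150.0, pref_vp2=150.0, kappa=2.0,
                         peak_vp1=20.0, peak_vp2=20.0),
            traj_20min, None, sched, seed=6)
        for cell, expect_hd in ((place, False), (hd, True)):
            curve = hd_tuning_curve(cell, traj_20min)
            m = firing_rate_map(cell, traj_20min)
            _, dr = distributive_ratio(curve, m)
            assert (dr > 0.2) == expect_hd

    def test_predicted_curve_flat_for_place_cell(self, traj_20min):
        # the distributive prediction must capture sampling-bias tuning
        sched = make_schedule(10, 120.0)
        place = simulate_hd_cell(
            HDCellParams(kappa=0.0, peak_vp1=1.0, peak_vp2=1.0, baseline=1.0,
                         place_field=(20.0, 50.0, 8.0, 15.0)),
            traj_20min, None, sched, seed=7)
        curve = hd_tuning_curve(place, traj_20min)
        pred, dr = distributive_ratio(curve, firing_rate_map(place, traj_20min))
        assert dr < 0.2
        assert np.corrcoef(curve.rate, pred.rate)[0, 1] > 0.5


class TestEgocentricBearing:
    def _static_traj(self, hd_deg, n=200):
        t = np.arange(n) * 0.02
        return Trajectory(t, np.full(n, 35.0), np.full(n, 35.0),
                          np.full(n, float(hd_deg)))

    def test_facing_landmark_gives_alpha_zero(self):
        traj = self._static_traj(0.0)  # landmark due east, hd = 0
        cell = SpikeTrain("c", "t1", traj.t[::4].copy())
        curve = egocentric_bearing_tuning(cell, traj, (70.0, 35.0),
                                          speed_min=None)
        assert np.argmax(curve.occupancy) == 0  # alpha in [0, 10) bin

    def test_hd_90_ccw_of_bearing_gives_alpha_270(self):
        traj = self._static_traj(90.0)
        cell = SpikeTrain("c", "t1", traj.t[::4].copy())
        curve = egocentric_bearing_tuning(cell, traj, (70.0, 35.0),
                                          speed_min=None)
        assert np.argmax(curve.occupancy) == 27  # 270-280 deg bin

    def test_landmark_at_infinity_mirrors_hd_tuning(self, traj_20min):
        cell = simulate_hd_cell(
            HDCellParams(pref_vp1=120.0, pref_vp2=120.0, kappa=2.0,
                         peak_vp1=20.0, peak_vp2=20.0),
            traj_20min, None, make_schedule(10, 120.0), seed=8)
        _, pref_hd = hd_score_and_preferred(hd_tuning_curve(cell, traj_20min))
        # a landmark 1e4 cm east has allocentric bearing ~0 everywhere, so
        # alpha = -hd and the egocentric preferred is the mirrored HD
        ego = egocentric_bearing_tuning(cell, traj_20min, (1e4, 35.0))
        _, pref_ego = hd_score_and_preferred(ego)
        assert circ_dist(pref_ego, wrap360(-pref_hd)) < 5.0

    def test_parallax_shifts_apparent_preferred_hd(self, traj_20min):
        # inhomogeneous Poisson cell tuned to the egocentric bearing of a
        # landmark at the platform center: its apparent preferred HD must
        # rotate across quadrants, unlike a true allocentric HD cell
        rng = np.random.default_rng(9)
        lam_max = 20.0
        n = rng.poisson(lam_max * 1200.0)
        cand = np.sort(rng.uniform(0, traj_20min.t[-1], n))
        ix = np.searchsorted(traj_20min.t, cand).clip(0, traj_20min.t.size - 1)
        phi = np.rad2deg(np.arctan2(35.0 - traj_20min.y[ix],
                                    35.0 - traj_20min.x[ix]))
        alpha = wrap360(phi - traj_20min.hd[ix])
        lam = lam_max * np.exp(2.0 * (np.cos(np.deg2rad(alpha)) - 1.0))
        ego_cell = SpikeTrain("ego", "t1",
                              cand[rng.uniform(0, lam_max, n) < lam])
        prefs = tuning.preferred_hd_shift_by_quadrant(ego_cell, traj_20min)
        vals = [v for v in prefs.values() if np.isfinite(v)]
        spread = max(circ_dist(a, b) for a in vals for b in vals)
        assert spread > 30.0

        hd_cell = simulate_hd_cell(
            HDCellParams(pref_vp1=40.0, pref_vp2=40.0, kappa=2.0,
                         peak_vp1=20.0, peak_vp2=20.0),
            traj_20min, None, make_schedule(10, 120.0), seed=10)
        prefs = tuning.preferred_hd_shift_by_quadrant(hd_cell, traj_20min)
        vals = [v for v in prefs.values() if np.isfinite(v)]
        spread = max(circ_dist(a, b) for a in vals for b in vals)
        assert spread < 15.0


class TestBidirectionality:
    def _two_peak_curve(self, p1, p2, t1, t2):
        rate = np.empty(36)
        rate[0:9] = np.linspace(p1, t1, 9)        # descend to trough 1
        rate[9:18] = np.linspace(t1, p2, 9)       # rise to peak 2
        rate[18:27] = np.linspace(p2, t2, 9)      # descend to trough 2
        rate[27:36] = np.linspace(t2, p1, 9)      # back up to peak 1
        rate[0] = p1
        rate[17] = p2
        return _curve(np.roll(rate, 2))

    def test_bd_score_is_peak_ratio(self):
        res = bd_scores(self._two_peak_curve(10.0, 5.0, 0.5, 0.5))
        assert res.bd_score == pytest.approx(0.5)
        assert res.p1 == 10.0 and res.p2 == 5.0

    def test_trough_rule(self):
        # troughs 1 and 3 Hz -> trough_max 3; 4/3 = 1.33 > 1.25 -> bidirectional
        res = bd_scores(self._two_peak_curve(8.0, 4.0, 1.0, 3.0))
        assert res.trough_rate == pytest.approx(3.0)
        assert res.is_bidirectional
        # trough at 3.5 Hz -> ratio 1.14 < 1.25 -> not bidirectional
        res2 = bd_scores(self._two_peak_curve(8.0, 4.0, 1.0, 3.5))
        assert not res2.is_bidirectional

    def test_single_peak_not_bidirectional(self):
        rate = np.exp(2.0 * np.cos(np.deg2rad(HD_BIN_CENTERS - 90.0))) * 3.0
        res = bd_scores(_curve(rate))
        assert res.bd_score == 0.0 and not res.is_bidirectional

    def test_unimodal_cells_rarely_flagged(self, traj_20min):
        sched = make_schedule(10, 120.0)
        flags = []
        for seed in range(10):
            cell = simulate_hd_cell(
                HDCellParams(pref_vp1=30.0 * seed, pref_vp2=30.0 * seed,
                             kappa=2.0, peak_vp1=20.0, peak_vp2=20.0),
                traj_20min, None, sched, seed=100 + seed)
            flags.append(bd_scores(hd_tuning_curve(cell, traj_20min)).is_bidirectional)
        assert sum(flags) <= 1


class TestMapCorrelations:
    @pytest.fixture()
    def grid_map(self, traj_20min):
        from parahd.synthetic import GridCellParams, simulate_grid_cell
        cell = simulate_grid_cell(GridCellParams(spacing=30.0), traj_20min,
                                  None, make_schedule(10, 120.0), seed=11)
        return firing_rate_map(cell, traj_20min, with_hd_occupancy=False)

    def test_identical_maps_r_one(self, grid_map):
        assert map_similarity(grid_map, grid_map) == pytest.approx(1.0)

    def test_permuted_map_uncorrelated(self, grid_map):
        rng = np.random.default_rng(12)
        rs = []
        flat = grid_map.rate.ravel().copy()
        for _ in range(100):
            perm = RateMap(2.0, rng.permutation(flat).reshape(35, 35),
                           grid_map.occupancy_s, grid_map.occupancy_p)
            rs.append(map_similarity(grid_map, perm))
        assert abs(np.mean(rs)) < 0.05

    def test_crosscorr_self_peaks_at_zero_lag(self, grid_map):
        cc = spatial_crosscorrelation(grid_map, grid_map)
        center = np.unravel_index(np.nanargmax(cc), cc.shape)
        assert center == (34, 34)
        assert cc[34, 34] == pytest.approx(1.0)

    def test_crosscorr_recovers_constructed_shift(self, grid_map):
        shifted = np.full_like(grid_map.rate, np.nan)
        shifted[2:, :] = grid_map.rate[:-2, :]   # shift by 2 bins = 4 cm in x
        b = RateMap(2.0, shifted, grid_map.occupancy_s, grid_map.occupancy_p)
        cc = spatial_crosscorrelation(grid_map, b)
        peak = np.unravel_index(np.nanargmax(cc), cc.shape)
        assert abs(peak[0] - 34) == 2 and peak[1] == 34

    def test_too_few_common_bins_undefined(self, grid_map):
        mostly_nan = np.full_like(grid_map.rate, np.nan)
        mostly_nan[:3, :3] = 1.0
        b = RateMap(2.0, mostly_nan, grid_map.occupancy_s, grid_map.occupancy_p)
        assert np.isnan(map_similarity(grid_map, b))
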