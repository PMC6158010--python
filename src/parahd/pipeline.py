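"""Whole-session orchestration: per-cell scores, classification, change
tests, pair tables and population summaries.

``run_pipeline`` is deterministic given (session, config, seed): every
randomised step draws from its own stream spawned from the master seed in a
fixed order, so re-running with the same inputs reproduces every table
bit-for-bit.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import landmark, pairs, rhythmicity, selectivity, tuning
from .config import PipelineConfig
from .core import (IFR_PRESET_BEHAVIOR, Session, SpikeTrain, compute_speed,
                   instantaneous_rate)
from .selectivity import ShuffleThreshold
from .tuning import N_MAP_BINS, MAP_BIN_CM, RateMap, _gauss2


@dataclass
class ResultsBundle:
    cells: pd.DataFrame
    pairs: pd.DataFrame
    grid_pairs: pd.DataFrame
    summary: dict
    log: dict


class _SessionCache:
    """Precomputed per-session quantities shared across cells and shuffles."""

    def __init__(self, session: Session, config: PipelineConfig):
        traj = session.trajectory
        self.traj = traj
        self.span = traj.span()
        self.sel = tuning._selected_samples(traj, config.speed_min_cms)
        self.dt = traj.dt
        ix = np.clip((traj.x / MAP_BIN_CM).astype(int), 0, N_MAP_BINS - 1)
        iy = np.clip((traj.y / MAP_BIN_CM).astype(int), 0, N_MAP_BINS - 1)
        self.flat_bin = ix * N_MAP_BINS + iy
        occ = np.bincount(self.flat_bin[self.sel],
                          minlength=N_MAP_BINS ** 2).astype(float) * self.dt
        self.occ = occ.reshape(N_MAP_BINS, N_MAP_BINS)
        sd_bins = tuning.MAP_SMOOTH_SD_CM / MAP_BIN_CM
        self.occ_sm = _gauss2(self.occ, sd_bins)
        self.valid = self.occ_sm > 1e-12
        self.den = _gauss2(self.valid.astype(float), sd_bins)
        self.sd_bins = sd_bins
        # speed at behavioral IFR window centers (for speed-score shuffles)
        speed = compute_speed(traj)
        good = np.isfinite(speed)
        sd, window = IFR_PRESET_BEHAVIOR
        n_win = int(np.floor((self.span[1] - self.span[0]) / window))
        self.ifr_t = self.span[0] + (np.arange(n_win) + 0.5) * window
        self.win_speed = np.interp(self.ifr_t, traj.t[good], speed[good])
        self.speed_ok = (self.win_speed > 3.0) & (self.win_speed < 100.0)

    def spike_counts_map(self, spike_times: np.ndarray) -> np.ndarray:
        idx = tuning.spike_sample_indices(spike_times, self.traj)
        keep = self.sel[idx]
        cnt = np.bincount(self.flat_bin[idx[keep]], minlength=N_MAP_BINS ** 2)
        return cnt.reshape(N_MAP_BINS, N_MAP_BINS).astype(float)

    def rate_map(self, spike_times: np.ndarray) -> RateMap:
        cnt = self.spike_counts_map(spike_times)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(self.valid, cnt / np.where(self.valid, self.occ_sm, 1.0), 0.0)
        rate = np.where(self.den > 0, _gauss2(raw, self.sd_bins)
                        / np.where(self.den > 0, self.den, 1.0), np.nan)
        rate[~self.valid] = np.nan
        occ_p = self.occ / self.occ.sum()
        return RateMap(MAP_BIN_CM, rate, self.occ, occ_p, valid=self.valid)

    def fast_ifr(self, spike_times: np.ndarray) -> np.ndarray:
        """Behavioral-preset IFR via Gaussian CDF mass per window (numerically
        equivalent to smoothing the 1-ms count vector, but O(spikes))."""
        sd, window = IFR_PRESET_BEHAVIOR
        t0 = self.span[0]
        n_win = self.ifr_t.size
        rate = np.zeros(n_win)
        if spike_times.size == 0:
            return rate
        reach = int(np.ceil(4 * sd / window)) + 1
        base = np.floor((spike_times - t0) / window).astype(int) - reach
        for k in range(2 * reach + 2):
            j = base + k
            ok = (j >= 0) & (j < n_win)
            if not ok.any():
                continue
            lo = t0 + j[ok] * window
            mass = (ndtr((lo + window - spike_times[ok]) / sd)
                    - ndtr((lo - spike_times[ok]) / sd))
            np.add.at(rate, j[ok], mass)
        return rate / window


def _shuffle_scores(cache, spikes, score_fns: dict, n, min_shift, rng):
    """Shared positional shuffle: one circular shift scores every function."""
    t0, t1 = cache.span
    total = t1 - t0
    null = {k: np.empty(n) for k in score_fns}
    for i in range(n):
        shift = rng.uniform(min_shift, total - min_shift)
        shifted = np.sort(t0 + np.mod(spikes.times - t0 + shift, total))
        for k, fn in score_fns.items():
            null[k][i] = fn(shifted)
    return null


def _threshold(observed, null, percentile) -> ShuffleThreshold:
    thr = float(np.nanpercentile(null, percentile))
    sig = bool(np.isfinite(observed) and observed > thr)
    return ShuffleThreshold(float(observed), null, thr, sig)


def run_pipeline(session: Session, config: PipelineConfig | None = None,
                 seed: int | None = None) -> ResultsBundle:
    """Run the full per-cell and per-pair analysis of one session."""
    t_start = time.time()
    config = config or PipelineConfig()
    master_seed = config.seed if seed is None else seed
    cache = _SessionCache(session, config)
    traj, schedule = session.trajectory, session.schedule
    span = cache.span
    cells = sorted(session.cells, key=lambda c: c.cell_id)
    streams = np.random.SeedSequence(master_seed).spawn(len(cells) + 1)

    rows = []
    summaries = {}
    ifrs = {}
    for ci, cell in enumerate(cells):
        rng = np.random.default_rng(streams[ci])
        row = {"cell_id": cell.cell_id, "tetrode_id": cell.tetrode_id,
               "n_spikes": cell.n,
               "mean_rate": cell.n / (span[1] - span[0])}

        sm = landmark.TrialSummaries.build(cell, traj, schedule,
                                           config.speed_min_cms)
        summaries[cell.cell_id] = sm
        change = landmark.condition_change_stats(cell, traj, schedule,
                                                 summaries=sm)
        row.update(hd_score_vp1=change.score_vp1, hd_score_vp2=change.score_vp2,
                   pref_vp1=change.pref_vp1, pref_vp2=change.pref_vp2,
                   hd_peak_vp1=change.peak_vp1, hd_peak_vp2=change.peak_vp2,
                   rate_vp1=change.r_vp1, rate_vp2=change.r_vp2,
                   d_pref=change.d_pref, d_score=change.d_score,
                   rel_rate=change.rel_rate)

        tests = landmark.trial_label_shuffle_tests(
            cell, traj, schedule, n=config.n_label_shuffles, rng=rng,
            summaries=sm)
        for k in landmark.STAT_NAMES:
            row[f"sig_{k}"] = tests[k].significant

        # spatial scores on the pooled map
        pooled_curve = sm.curve(np.arange(len(schedule)))
        rate_map = tuning.firing_rate_map(cell, traj, config.speed_min_cms)
        _, dr = tuning.distributive_ratio(pooled_curve, rate_map)
        row["distributive_ratio"] = dr
        row["sparsity"] = selectivity.sparsity_score(rate_map)
        ac = selectivity.spatial_autocorrelation(cache.rate_map(cell.times))
        row["grid_score"] = selectivity.grid_score(ac).grid_score

        ifr = instantaneous_rate(cell, span=span)
        ifrs[cell.cell_id] = ifr
        try:
            row["speed_r"] = selectivity.speed_score(cell, traj)
        except ValueError:
            row["speed_r"] = np.nan

        def grid_fn(times):
            m = cache.rate_map(times)
            return selectivity.grid_score(selectivity.spatial_autocorrelation(m)).grid_score

        def sparsity_fn(times):
            return selectivity.sparsity_score(cache.rate_map(times))

        def speed_fn(times):
            r = cache.fast_ifr(times)[cache.speed_ok]
            s = cache.win_speed[cache.speed_ok]
            if r.std() == 0:
                return np.nan
            return float(np.corrcoef(s, r)[0, 1])

        null = _shuffle_scores(cache, cell,
                               {"grid": grid_fn, "sparsity": sparsity_fn,
                                "speed": speed_fn},
                               config.n_positional_shuffles,
                               config.min_shift_s, rng)
        for name, obs in (("grid", row["grid_score"]),
                          ("sparsity", row["sparsity"]),
                          ("speed", row["speed_r"])):
            th = _threshold(obs, null[name], config.shuffle_percentile)
            row[f"{name}_thr"] = th.threshold
            row[f"{name}_significant"] = th.significant

        spec = rhythmicity.rate_power_spectrum(cell, span)
        row["theta_index"] = rhythmicity.theta_index(spec)

        try:
            ach = rhythmicity.spike_time_autocorrelation(cell)
            row["skipping_index"], row["is_skipping"] = \
                rhythmicity.theta_skipping_index(ach, config.skipping_threshold)
        except ValueError:
            row["skipping_index"], row["is_skipping"] = np.nan, False

        bd1, bd2, bd_flag = tuning.bd_analysis(change.curve_vp1, change.curve_vp2)
        row.update(bd_score_vp1=bd1.bd_score, bd_score_vp2=bd2.bd_score,
                   is_bidirectional=bd_flag)
        rows.append(row)

    cells_df = pd.DataFrame(rows).set_index("cell_id", drop=False)
    cells_df["label"] = selectivity.classify_cells(cells_df)

    # theta-rhythmicity class of HD cells: mixture threshold unless overridden
    hd_mask = cells_df["label"].isin(["HD"])
    theta_thr = config.theta_index_threshold
    mixture_info = None
    if theta_thr is None:
        idx_vals = cells_df.loc[hd_mask, "theta_index"].dropna().to_numpy()
        if idx_vals.size >= 10:
            fit = rhythmicity.fit_theta_index_mixture(idx_vals, seed=master_seed)
            if fit.k == 2 and np.isfinite(fit.threshold):
                theta_thr = fit.threshold
            mixture_info = {"k": fit.k, "threshold": fit.threshold,
                            "bic": fit.bic}
        if theta_thr is None:
            theta_thr = 0.07
    cells_df["rhythm_class"] = np.where(
        cells_df["theta_index"] > theta_thr, "theta-rhythmic", "non-rhythmic")

    # HD cell pairs: reorganization + theta synchrony
    pair_rows = []
    hd_ids = list(cells_df.index[hd_mask])
    pair_rng = np.random.default_rng(streams[-1])
    for a in range(len(hd_ids)):
        for b in range(a + 1, len(hd_ids)):
            ci, cj = hd_ids[a], hd_ids[b]
            res = pairs.reorganization_scores(
                summaries[ci], summaries[cj], schedule,
                ifrs[ci], ifrs[cj], pair=(ci, cj))
            lags, z = pairs.crosscorr_z(session.cell(ci), session.cell(cj))
            sync = pairs.theta_synchrony(lags, z,
                                         threshold=config.synchrony_threshold)
            cls_i = cells_df.loc[ci, "rhythm_class"]
            cls_j = cells_df.loc[cj, "rhythm_class"]
            pair_rows.append({
                "cell_i": ci, "cell_j": cj,
                "pair_class": cls_i if cls_i == cls_j else "mixed",
                "between_pref": res.between_pref, "within_pref": res.within_pref,
                "between_score": res.between_score, "within_score": res.within_score,
                "between_ifr": res.between_ifr, "within_ifr": res.within_ifr,
                "synchrony": sync.score,
            })
    pairs_df = pd.DataFrame(pair_rows)
    sync_threshold = float(config.synchrony_threshold)
    if len(pairs_df) >= 10:
        # re-derive the LTS/HTS boundary from the cohort's score distribution
        sync_threshold = pairs.derive_synchrony_threshold(
            pairs_df["synchrony"].to_numpy(), seed=master_seed)
    if len(pairs_df):
        pairs_df["synchrony_class"] = np.where(
            pairs_df["synchrony"] > sync_threshold, "HTS", "LTS")

    # grid cell pairs: IFR association + pairwise map similarity coherence
    grid_rows = []
    grid_ids = list(cells_df.index[cells_df["label"] == "grid"])
    subset_maps = {}
    for cid in grid_ids:
        cell = session.cell(cid)
        subset_maps[cid] = {
            name: tuning.firing_rate_map(
                cell, traj, config.speed_min_cms,
                intervals=schedule.select(trial_indices=idx),
                with_hd_occupancy=False)
            for name, idx in pairs._subsets(schedule).items()}
    for a in range(len(grid_ids)):
        for b in range(a + 1, len(grid_ids)):
            ci, cj = grid_ids[a], grid_ids[b]
            g = pairs.grid_pair_coherence(subset_maps[ci], subset_maps[cj],
                                          ifrs[ci], ifrs[cj], schedule,
                                          pair=(ci, cj))
            grid_rows.append({
                "cell_i": ci, "cell_j": cj,
                "between_map": g.between_map, "within_map": g.within_map,
                "between_ifr": g.between_ifr, "within_ifr": g.within_ifr,
            })
    grid_pairs_df = pd.DataFrame(grid_rows)

    hd_cells = cells_df[hd_mask]
    summary = {
        "n_cells": len(cells_df),
        "labels": cells_df["label"].value_counts().to_dict(),
        "theta_index_threshold": float(theta_thr),
        "mixture": mixture_info,
        "population": (landmark.summarize_population(hd_cells).to_dict("records")
                       if len(hd_cells) else []),
        "synchrony_threshold": float(sync_threshold),
        "n_hd_pairs": len(pairs_df),
        "n_grid_pairs": len(grid_pairs_df),
    }
    log = {"seed": int(master_seed),
           "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
           "runtime_s": round(time.time() - t_start, 2)}
    return ResultsBundle(cells_df, pairs_df, grid_pairs_df, summary, log)
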