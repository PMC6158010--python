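"""Reproduction experiments: calibrations and end-to-end checks.

These functions bundle the standard validation experiments of the package:
shuffle-test calibration on no-effect cells, power against a known rotation,
mixture-based rhythmicity classification of simulated theta indices, the
reorganization dissociation between coherent theta-rhythmic and
independently rotating non-rhythmic HD-cell cohorts, and end-to-end
parameter recovery on a default synthetic session.  They are used by the
test suite and the reproduction script, and are handy for sensitivity
analyses at other problem sizes.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import wilcoxon

from ._circular import circ_dist
from .core import instantaneous_rate
from .landmark import STAT_NAMES, TrialSummaries, trial_label_shuffle_tests
from .pairs import _subsets, grid_pair_coherence, reorganization_scores
from .rhythmicity import fit_theta_index_mixture, rate_power_spectrum, theta_index
from .synthetic import (GridCellParams, HDCellParams, make_schedule,
                        simulate_grid_cell, simulate_hd_cell,
                        simulate_trajectory)


def shuffle_calibration(n_null_cells: int = 200, n_rotated_cells: int = 30,
                        n_shuffles: int = 500, rotation_deg: float = 90.0,
                        seed: int = 0) -> dict:
    """Type-I error and power of the trial-label shuffle tests.

    No-effect HD cells (kappa=2, 20 Hz peak, stationary across conditions)
    estimate the per-statistic false-positive rate; cells whose preferred
    direction rotates by ``rotation_deg`` in vp2 estimate the power of the
    preferred-direction test.  Every cell gets its own trajectory so the
    per-cell outcomes are independent and the observed rates binomial.
    """
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(3 * (n_null_cells + n_rotated_cells))
    sched = make_schedule(40, 120.0)
    hits = {k: 0 for k in STAT_NAMES}
    si = 0
    for i in range(n_null_cells):
        pref = (i * 360.0 / max(n_null_cells, 1)) % 360.0
        traj = simulate_trajectory(sched.ends[-1], seed=streams[si]); si += 1
        cell = simulate_hd_cell(
            HDCellParams(pref_vp1=pref, pref_vp2=pref, kappa=2.0,
                         peak_vp1=20.0, peak_vp2=20.0),
            traj, None, sched, seed=streams[si]); si += 1
        res = trial_label_shuffle_tests(cell, traj, sched, n=n_shuffles,
                                        rng=np.random.default_rng(streams[si]))
        si += 1
        for k in STAT_NAMES:
            hits[k] += res[k].significant

    power_hits = 0
    for i in range(n_rotated_cells):
        pref = (i * 360.0 / max(n_rotated_cells, 1)) % 360.0
        traj = simulate_trajectory(sched.ends[-1], seed=streams[si]); si += 1
        cell = simulate_hd_cell(
            HDCellParams(pref_vp1=pref,
                         pref_vp2=(pref + rotation_deg) % 360.0,
                         kappa=2.0, peak_vp1=20.0, peak_vp2=20.0),
            traj, None, sched, seed=streams[si]); si += 1
        res = trial_label_shuffle_tests(cell, traj, sched, n=n_shuffles,
                                        rng=np.random.default_rng(streams[si]))
        si += 1
        power_hits += res["d_pref"].significant

    return {
        "fpr": {k: hits[k] / n_null_cells for k in STAT_NAMES},
        "fpr_pooled": sum(hits.values()) / (3 * n_null_cells),
        "power_d_pref": power_hits / n_rotated_cells,
        "n_null_cells": n_null_cells,
        "n_rotated_cells": n_rotated_cells,
        "n_shuffles": n_shuffles,
    }


def theta_mixture_experiment(n_nonrhythmic: int = 34, n_rhythmic: int = 59,
                             duration: float = 600.0, seed: int = 0) -> dict:
    """Theta indices of simulated non-rhythmic (depth 0) and theta-rhythmic
    (depth 0.8) HD cells, classified by the Gaussian-mixture fit."""
    from .synthetic import simulate_lfp

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_nonrhythmic + n_rhythmic + 2)
    n_trials = int(duration // 120)
    sched = make_schedule(max(n_trials, 2), 120.0)
    traj = simulate_trajectory(duration, seed=streams[0])
    _, phase = simulate_lfp(duration, seed=streams[1])
    indices, truth = [], []
    for i in range(n_nonrhythmic + n_rhythmic):
        rhythmic = i >= n_nonrhythmic
        pref = (i * 77.0) % 360.0
        cell = simulate_hd_cell(
            HDCellParams(pref_vp1=pref, pref_vp2=pref, kappa=2.0,
                         peak_vp1=20.0, peak_vp2=20.0,
                         theta_depth=0.8 if rhythmic else 0.0,
                         theta_phase=(i * 53.0) % 360.0),
            traj, phase, sched, seed=streams[2 + i])
        spec = rate_power_spectrum(cell, (0.0, duration))
        indices.append(theta_index(spec))
        truth.append(int(rhythmic))
    indices = np.asarray(indices)
    truth = np.asarray(truth)
    fit = fit_theta_index_mixture(indices, seed=seed)
    accuracy = float(np.mean(fit.labels == truth)) if fit.k == 2 else np.nan
    return {"fit": fit, "indices": indices, "truth": truth,
            "k": fit.k, "threshold": fit.threshold, "accuracy": accuracy}


def _hd_pair_table(cells, traj, sched, with_ifr=True):
    sms = [TrialSummaries.build(c, traj, sched) for c in cells]
    ifrs = ([instantaneous_rate(c, span=traj.span()) for c in cells]
            if with_ifr else [None] * len(cells))
    rows = []
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            rows.append(reorganization_scores(sms[a], sms[b], sched,
                                              ifrs[a], ifrs[b]))
    return rows


def dissociation_experiment(n_seeds: int = 10, n_cells_per_class: int = 7,
                            n_grid: int = 4, seed: int = 0) -> dict:
    """Reorganization dissociation between cohorts, pooled across sessions.

    Each session holds theta-rhythmic HD cells rotating coherently by 30
    degrees in vp2, non-rhythmic HD cells with independent rotations
    (45-135 deg, random sign) and rate gains, and condition-stable grid
    cells.  Pairs are pooled over sessions and the between- vs
    within-condition reorganization compared with a one-sided paired
    Wilcoxon test (between > within).
    """
    from .synthetic import simulate_lfp
    from .tuning import firing_rate_map

    results = {"rhythmic": {k: ([], []) for k in ("pref", "score", "ifr")},
               "nonrhythmic": {k: ([], []) for k in ("pref", "score", "ifr")},
               "grid": {k: ([], []) for k in ("map", "ifr")}}
    ss = np.random.SeedSequence(seed)
    for sess_stream in ss.spawn(n_seeds):
        streams = sess_stream.spawn(2 * n_cells_per_class + n_grid + 3)
        sched = make_schedule(40, 120.0)
        traj = simulate_trajectory(sched.ends[-1], seed=streams[0])
        _, phase = simulate_lfp(sched.ends[-1], seed=streams[1])
        assign = np.random.default_rng(streams[2])
        si = 3

        coh = []
        for _ in range(n_cells_per_class):
            pref = assign.uniform(0, 360)
            coh.append(simulate_hd_cell(
                HDCellParams(pref_vp1=pref, pref_vp2=(pref + 30.0) % 360,
                             kappa=2.0, peak_vp1=20.0, peak_vp2=20.0,
                             theta_depth=0.8,
                             theta_phase=assign.uniform(0, 360)),
                traj, phase, sched, seed=streams[si])); si += 1
        ind = []
        for _ in range(n_cells_per_class):
            pref = assign.uniform(0, 360)
            rot = assign.uniform(45, 135) * assign.choice([-1.0, 1.0])
            gain = assign.uniform(0.4, 1.0)
            ind.append(simulate_hd_cell(
                HDCellParams(pref_vp1=pref, pref_vp2=(pref + rot) % 360,
                             kappa=2.0, peak_vp1=20.0, peak_vp2=20.0 * gain,
                             theta_depth=0.0),
                traj, None, sched, seed=streams[si])); si += 1

        for name, rows in (("rhythmic", _hd_pair_table(coh, traj, sched)),
                           ("nonrhythmic", _hd_pair_table(ind, traj, sched))):
            for r in rows:
                for key, b, w in (("pref", r.between_pref, r.within_pref),
                                  ("score", r.between_score, r.within_score),
                                  ("ifr", r.between_ifr, r.within_ifr)):
                    if np.isfinite(b) and np.isfinite(w):
                        results[name][key][0].append(b)
                        results[name][key][1].append(w)

        if n_grid >= 2:
            grids, maps, ifrs = [], {}, {}
            for g in range(n_grid):
                cid = f"g{g}"
                cell = simulate_grid_cell(
                    GridCellParams(spacing=assign.uniform(28, 40),
                                   orientation=assign.uniform(0, 60),
                                   phase_x=assign.uniform(0, 40),
                                   phase_y=assign.uniform(0, 40)),
                    traj, None, sched, seed=streams[si], cell_id=cid); si += 1
                grids.append(cell)
                maps[cid] = {
                    name: firing_rate_map(cell, traj,
                                          intervals=sched.select(trial_indices=idx),
                                          with_hd_occupancy=False)
                    for name, idx in _subsets(sched).items()}
                ifrs[cid] = instantaneous_rate(cell, span=traj.span())
            for a in range(len(grids)):
                for b in range(a + 1, len(grids)):
                    ca, cb = grids[a].cell_id, grids[b].cell_id
                    g = grid_pair_coherence(maps[ca], maps[cb],
                                            ifrs[ca], ifrs[cb], sched)
                    for key, bb, ww in (("map", g.between_map, g.within_map),
                                        ("ifr", g.between_ifr, g.within_ifr)):
                        if np.isfinite(bb) and np.isfinite(ww):
                            results["grid"][key][0].append(bb)
                            results["grid"][key][1].append(ww)

    pvals = {}
    for name, stats in results.items():
        pvals[name] = {}
        for key, (between, within) in stats.items():
            if len(between) < 5:
                pvals[name][key] = np.nan
                continue
            pvals[name][key] = float(
                wilcoxon(between, within, alternative="greater").pvalue)
    return {"pvalues": pvals, "data": results}


def recovery_experiment(seed: int = 0, config=None) -> dict:
    """End-to-end parameter recovery on the default 20-cell, 80-min session."""
    from .config import PipelineConfig
    from .pipeline import run_pipeline
    from .synthetic import build_synthetic_session

    session, truth = build_synthetic_session(seed=seed)
    bundle = run_pipeline(session, config or PipelineConfig(),
                          seed=seed + 1)
    df = bundle.cells
    want = {"hd_rhythmic": "HD", "hd_nonrhythmic": "HD", "grid": "grid",
            "untuned": "other"}
    n_correct = sum(df.loc[cid, "label"] == want[v["kind"]]
                    for cid, v in truth.cells.items())

    pref_errors, rot_errors, rhythm_correct, rhythm_total = [], [], 0, 0
    for cid, v in truth.cells.items():
        if not v["kind"].startswith("hd_"):
            continue
        p = v["params"]
        pref_errors.append(circ_dist(df.loc[cid, "pref_vp1"], p["pref_vp1"]))
        true_rot = abs(v["rotation_deg"])
        if true_rot > 180.0:
            true_rot = 360.0 - true_rot
        rot_errors.append(abs(df.loc[cid, "d_pref"] - true_rot))
        rhythm_total += 1
        expected = ("theta-rhythmic" if v["kind"] == "hd_rhythmic"
                    else "non-rhythmic")
        rhythm_correct += df.loc[cid, "rhythm_class"] == expected

    return {
        "bundle": bundle,
        "truth": truth,
        "accuracy": n_correct / len(truth.cells),
        "n_cells": len(truth.cells),
        "pref_error_deg": np.asarray(pref_errors),
        "rotation_error_deg": np.asarray(rot_errors),
        "rhythm_accuracy": rhythm_correct / max(rhythm_total, 1),
    }
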