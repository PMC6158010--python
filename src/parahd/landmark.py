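"""Visually driven tuning changes between the vp1 and vp2 conditions.

For each cell, HD tuning curves are computed from the concatenated vp1 and
vp2 trials, and three change statistics are derived: the circular change in
preferred direction, the absolute change in HD score (mean vector length),
and the relative change in mean firing rate |r1 - r2|/(r1 + r2).

Significance is assessed with a cell-specific trial-label shuffle: the
vp1/vp2 labels of the forty 2-min trials are reassigned randomly (preserving
the 20/20 balance by default), the statistics recomputed, and the observed
change is significant when it exceeds 99% of the surrogate changes.

Per-trial HD histograms are precomputed once so that each surrogate only
re-sums 36-bin histograms, making 500 shuffles cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from ._circular import circ_dist
from .core import SpikeTrain, Trajectory, TrialSchedule
from .tuning import (SPEED_MIN_CMS, HDTuningCurve, _selected_samples,
                     angular_histograms, curve_from_histograms,
                     hd_score_and_preferred, spike_sample_indices)

#: preferred direction is undefined below this HD score
MIN_SCORE_FOR_PREF = 0.05


@dataclass
class TrialSummaries:
    """Per-trial HD occupancy/count histograms and spike counts of one cell."""

    occ: np.ndarray        # (n_trials, 36) seconds, speed-filtered
    cnt: np.ndarray        # (n_trials, 36) spike counts, speed-filtered
    n_spikes: np.ndarray   # (n_trials,) total spikes in trial
    duration: np.ndarray   # (n_trials,) trial length, s
    conditions: np.ndarray

    @classmethod
    def build(cls, spikes: SpikeTrain, traj: Trajectory,
              schedule: TrialSchedule, speed_min: float = SPEED_MIN_CMS):
        sel = _selected_samples(traj, speed_min)
        idx = spike_sample_indices(spikes.times, traj)
        n = len(schedule)
        occ = np.zeros((n, 36))
        cnt = np.zeros((n, 36))
        nspk = np.zeros(n)
        dur = schedule.ends - schedule.starts
        for i in range(n):
            s, e = schedule.starts[i], schedule.ends[i]
            in_trial = (traj.t >= s) & (traj.t < e)
            sp_in = (spikes.times >= s) & (spikes.times < e)
            nspk[i] = sp_in.sum()
            keep = sp_in & sel[idx]
            occ[i], cnt[i] = angular_histograms(
                traj.hd[in_trial & sel], traj.dt, traj.hd[idx[keep]])
        return cls(occ, cnt, nspk, dur, schedule.conditions.copy())

    def curve(self, trial_idx) -> HDTuningCurve:
        trial_idx = np.asarray(trial_idx, dtype=int)
        return curve_from_histograms(self.occ[trial_idx].sum(axis=0),
                                     self.cnt[trial_idx].sum(axis=0))

    def mean_rate(self, trial_idx) -> float:
        trial_idx = np.asarray(trial_idx, dtype=int)
        total = self.duration[trial_idx].sum()
        if total <= 0:
            raise ValueError("zero time in the selected trials")
        return float(self.n_spikes[trial_idx].sum() / total)

    def change_stats(self, idx1, idx2):
        """(d_pref, d_score, rel_rate) between two trial subsets."""
        c1, c2 = self.curve(idx1), self.curve(idx2)
        s1, p1 = hd_score_and_preferred(c1)
        s2, p2 = hd_score_and_preferred(c2)
        d_pref = (float(circ_dist(p1, p2))
                  if s1 >= MIN_SCORE_FOR_PREF and s2 >= MIN_SCORE_FOR_PREF
                  else np.nan)
        d_score = abs(s1 - s2)
        r1, r2 = self.mean_rate(idx1), self.mean_rate(idx2)
        rel = abs(r1 - r2) / (r1 + r2) if (r1 + r2) > 0 else np.nan
        return d_pref, d_score, rel


@dataclass
class ConditionChange:
    curve_vp1: HDTuningCurve
    curve_vp2: HDTuningCurve
    score_vp1: float
    score_vp2: float
    pref_vp1: float
    pref_vp2: float
    peak_vp1: float
    peak_vp2: float
    r_vp1: float
    r_vp2: float
    d_pref: float
    d_score: float
    rel_rate: float


@dataclass
class ShuffleTestResult:
    observed: float
    null: np.ndarray
    p_rank: float              # fraction of surrogates >= observed
    significant: bool


STAT_NAMES = ("d_pref", "d_score", "rel_rate")


def condition_change_stats(
    spikes: SpikeTrain, traj: Trajectory, schedule: TrialSchedule,
    speed_min: float = SPEED_MIN_CMS,
    summaries: TrialSummaries | None = None,
) -> ConditionChange:
    """Per-cell vp1-vs-vp2 tuning curves and change statistics."""
    sm = summaries or TrialSummaries.build(spikes, traj, schedule, speed_min)
    i1 = schedule.trial_indices("vp1")
    i2 = schedule.trial_indices("vp2")
    if i1.size == 0 or i2.size == 0:
        raise ValueError("both conditions need at least one trial")
    c1, c2 = sm.curve(i1), sm.curve(i2)
    s1, p1 = hd_score_and_preferred(c1)
    s2, p2 = hd_score_and_preferred(c2)
    d_pref, d_score, rel = sm.change_stats(i1, i2)
    return ConditionChange(
        c1, c2, s1, s2, p1, p2, c1.peak_rate, c2.peak_rate,
        sm.mean_rate(i1), sm.mean_rate(i2), d_pref, d_score, rel)


def _significant(observed: float, null: np.ndarray, percent: float = 99.0):
    """Strict exceedance rule: observed must be larger than ceil(q*n) of the
    sorted surrogates (NaN surrogates cannot exceed anything)."""
    if not np.isfinite(observed):
        return np.nan, False
    clean = np.where(np.isfinite(null), null, -np.inf)
    n = clean.size
    order_stat = np.sort(clean)[ceil(percent / 100.0 * n) - 1]
    p_rank = float(np.mean(clean >= observed))
    return p_rank, bool(observed > order_stat)


def trial_label_shuffle_tests(
    spikes: SpikeTrain | None,
    traj: Trajectory | None,
    schedule: TrialSchedule,
    n: int = 500,
    rng: np.random.Generator | int | None = None,
    preserve_counts: bool = True,
    speed_min: float = SPEED_MIN_CMS,
    summaries: TrialSummaries | None = None,
) -> dict[str, ShuffleTestResult]:
    """Shuffle test of all three change statistics for one cell.

    Returns a dict with keys ``d_pref``, ``d_score`` and ``rel_rate``.  The
    surrogate label assignment preserves the 20/20 condition balance unless
    ``preserve_counts`` is False (free reassignment).
    """
    n_vp1 = int(np.sum(schedule.conditions == "vp1"))
    n_vp2 = len(schedule) - n_vp1
    if min(n_vp1, n_vp2) < 4:
        raise ValueError("need at least 4 trials per condition")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sm = summaries or TrialSummaries.build(spikes, traj, schedule, speed_min)
    i1 = schedule.trial_indices("vp1")
    i2 = schedule.trial_indices("vp2")
    observed = dict(zip(STAT_NAMES, sm.change_stats(i1, i2)))

    null = {k: np.empty(n) for k in STAT_NAMES}
    n_trials = len(schedule)
    for s in range(n):
        if preserve_counts:
            perm = rng.permutation(n_trials)
            a, b = perm[:n_vp1], perm[n_vp1:]
        else:
            lab = rng.integers(0, 2, size=n_trials)
            a, b = np.flatnonzero(lab == 0), np.flatnonzero(lab == 1)
            if a.size == 0 or b.size == 0:
                a, b = np.array([0]), np.arange(1, n_trials)
        vals = sm.change_stats(a, b)
        for k, v in zip(STAT_NAMES, vals):
            null[k][s] = v

    out = {}
    for k in STAT_NAMES:
        p_rank, sig = _significant(observed[k], null[k])
        out[k] = ShuffleTestResult(observed[k], null[k], p_rank, sig)
    return out


def summarize_population(results) -> "pd.DataFrame":
    """Fractions of cells with significant changes, per rhythmicity class.

    ``results`` is a DataFrame with one row per cell and boolean columns
    ``sig_d_pref``, ``sig_d_score``, ``sig_rel_rate`` plus a
    ``rhythm_class`` column; the any-change column is the union of the
    three flags.
    """
    import pandas as pd

    df = results.copy()
    df["sig_any"] = df[["sig_d_pref", "sig_d_score", "sig_rel_rate"]].any(axis=1)
    rows = []
    for cls, grp in df.groupby("rhythm_class"):
        n = len(grp)
        row = {"rhythm_class": cls, "n_cells": n}
        for col in ("sig_d_pref", "sig_d_score", "sig_rel_rate", "sig_any"):
            count = int(grp[col].sum())
            row[f"{col}_count"] = count
            row[f"{col}_frac"] = count / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
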