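"""Grid, sparsity and speed scores; positional-shuffle thresholds; cell typing.

Grid periodicity is quantified on the spatial autocorrelation of the firing
rate map: the annular region containing up to six first-order peaks (central
peak excluded) is correlated with rotated copies of itself and

    grid score = (r60 + r120) / 2 - (r30 + r90 + r150) / 3.

Score significance uses cell-specific null distributions obtained by
circularly shifting the tracking data relative to the spike train by at
least 20 s (99th percentile threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import SpikeTrain, Trajectory, compute_speed, instantaneous_rate
from .tuning import RateMap, lagged_pearson

PEAK_AC_THRESHOLD = 0.1
PEAK_MIN_BINS = 10          # component must exceed this many bins
GRID_ROTATIONS_DEG = (30, 60, 90, 120, 150)


@dataclass
class AutocorrPeak:
    row: int
    col: int
    value: float
    size: int
    dist_from_center: float
    is_central: bool


@dataclass
class GridScoreResult:
    autocorr: np.ndarray
    peaks: list
    inner_radius: float
    outer_radius: float
    rotation_r: dict
    grid_score: float


@dataclass
class ShuffleThreshold:
    observed: float
    null: np.ndarray
    threshold: float
    significant: bool


def spatial_autocorrelation(rate_map: RateMap, min_overlap: int = 20) -> np.ndarray:
    """Pearson-r spatial autocorrelation matrix of a firing rate map."""
    return lagged_pearson(rate_map.rate, rate_map.rate, min_overlap)


def autocorr_peaks(ac: np.ndarray) -> list[AutocorrPeak]:
    """Connected components (4-connectivity) of bins > 0.1 larger than 10 bins.

    Each peak is located at its maximum bin; the component containing the
    zero-lag bin is flagged central.
    """
    mask = np.isfinite(ac) & (ac > PEAK_AC_THRESHOLD)
    labels, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    center = ((ac.shape[0] - 1) // 2, (ac.shape[1] - 1) // 2)
    central_label = labels[center] if mask[center] else -1
    peaks = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size <= PEAK_MIN_BINS:
            continue
        vals = ac[rows, cols]
        k = int(np.argmax(vals))
        r, c = int(rows[k]), int(cols[k])
        peaks.append(AutocorrPeak(
            row=r, col=c, value=float(vals[k]), size=int(rows.size),
            dist_from_center=float(np.hypot(r - center[0], c - center[1])),
            is_central=(lab == central_label),
        ))
    peaks.sort(key=lambda p: p.dist_from_center)
    return peaks


def _central_extent(ac: np.ndarray) -> float:
    """Distance from center at which the central > 0.1 component ends."""
    mask = np.isfinite(ac) & (ac > PEAK_AC_THRESHOLD)
    labels, _ = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    center = ((ac.shape[0] - 1) // 2, (ac.shape[1] - 1) // 2)
    if not mask[center]:
        return 1.0
    rows, cols = np.nonzero(labels == labels[center])
    return float(np.hypot(rows - center[0], cols - center[1]).max())


def grid_score(ac: np.ndarray, peaks: list[AutocorrPeak] | None = None) -> GridScoreResult:
    """Rotational 60-deg periodicity of a spatial autocorrelation matrix.

    The annulus runs from just outside the central peak to just beyond the
    6th-nearest non-central peak (or the outermost available); rotated
    values are sampled with bilinear interpolation.  Returns NaN score when
    no non-central peak exists.
    """
    if peaks is None:
        peaks = autocorr_peaks(ac)
    center = ((ac.shape[0] - 1) // 2, (ac.shape[1] - 1) // 2)
    ring = [p for p in peaks if not p.is_central][:6]
    if not ring:
        return GridScoreResult(ac, peaks, np.nan, np.nan, {}, np.nan)
    inner = _central_extent(ac)
    half_width = float(np.mean([np.sqrt(p.size / np.pi) for p in ring]))
    outer = min(ring[-1].dist_from_center + half_width,
                float(min(center)))  # stay inside the matrix
    rows, cols = np.indices(ac.shape)
    dist = np.hypot(rows - center[0], cols - center[1])
    annulus = (dist > inner) & (dist <= outer) & np.isfinite(ac)
    ar, acol = np.nonzero(annulus)
    base = ac[ar, acol]
    rot_r = {}
    for ang in GRID_ROTATIONS_DEG:
        th = np.deg2rad(ang)
        dr = ar - center[0]
        dc = acol - center[1]
        rr = center[0] + np.cos(th) * dr - np.sin(th) * dc
        rc = center[1] + np.sin(th) * dr + np.cos(th) * dc
        sampled = ndimage.map_coordinates(
            np.nan_to_num(ac, nan=0.0), [rr, rc], order=1, mode="constant", cval=np.nan)
        finite_mask = ndimage.map_coordinates(
            np.isfinite(ac).astype(float), [rr, rc], order=1, mode="constant", cval=0.0)
        ok = np.isfinite(sampled) & (finite_mask > 0.999)
        if ok.sum() < 20 or base[ok].std() == 0 or sampled[ok].std() == 0:
            rot_r[ang] = np.nan
        else:
            rot_r[ang] = float(np.corrcoef(base[ok], sampled[ok])[0, 1])
    score = ((rot_r.get(60, np.nan) + rot_r.get(120, np.nan)) / 2.0
             - (rot_r.get(30, np.nan) + rot_r.get(90, np.nan) + rot_r.get(150, np.nan)) / 3.0)
    return GridScoreResult(ac, peaks, inner, outer, rot_r, float(score))


def grid_score_of_map(rate_map: RateMap) -> float:
    """Convenience: autocorrelation -> peaks -> grid score."""
    ac = spatial_autocorrelation(rate_map)
    return grid_score(ac).grid_score


def sparsity_score(rate_map: RateMap) -> float:
    """Spatial sparsity, oriented so high values mean high sparsity:

        1 - (sum p_i lambda_i)^2 / sum p_i lambda_i^2

    with p_i the occupancy probability and lambda_i the firing rate of
    spatial bin i (invalid bins excluded, p renormalised).
    """
    ok = np.isfinite(rate_map.rate) & (rate_map.occupancy_s > 0)
    lam = rate_map.rate[ok]
    p = rate_map.occupancy_s[ok]
    p = p / p.sum()
    m2 = np.sum(p * lam * lam)
    if m2 <= 0:
        return np.nan
    m1 = np.sum(p * lam)
    return float(1.0 - m1 * m1 / m2)


def speed_score(spikes: SpikeTrain, traj: Trajectory,
                speed_range=(3.0, 100.0), min_windows: int = 100) -> float:
    """Pearson correlation between running speed and the IFR (sd 200 ms,
    100 ms windows), over windows with speed inside ``speed_range`` cm/s."""
    span = traj.span()
    ifr = instantaneous_rate(spikes, span=span)
    speed = compute_speed(traj)
    good = np.isfinite(speed)
    sp = np.interp(ifr.t, traj.t[good], speed[good])
    ok = (sp > speed_range[0]) & (sp < speed_range[1])
    if ok.sum() < min_windows:
        raise ValueError("too few qualifying speed windows")
    r_vals = ifr.rate[ok]
    if r_vals.std() == 0 or sp[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(sp[ok], r_vals)[0, 1])


def circular_shift_times(times: np.ndarray, span: tuple[float, float],
                         shift: float) -> np.ndarray:
    """Circularly shift event times within a span (wrap-around)."""
    t0, t1 = span
    total = t1 - t0
    return np.sort(t0 + np.mod(times - t0 + shift, total))


def positional_shuffle_threshold(
    observed: float,
    spikes: SpikeTrain,
    span: tuple[float, float],
    score_fn,
    n: int = 100,
    min_shift: float = 20.0,
    rng: np.random.Generator | None = None,
) -> ShuffleThreshold:
    """Cell-specific significance threshold from circular time shifts.

    ``score_fn`` receives a shifted :class:`SpikeTrain` and returns a
    scalar score.  Shifts are uniform in [min_shift, T - min_shift]; the
    threshold is the 99th percentile of the ``n`` surrogate scores.
    """
    t0, t1 = span
    total = t1 - t0
    if total < 2 * min_shift:
        raise ValueError("session too short for the minimum shuffle shift")
    rng = np.random.default_rng() if rng is None else rng
    null = np.empty(n)
    for i in range(n):
        shift = rng.uniform(min_shift, total - min_shift)
        shifted = SpikeTrain(spikes.cell_id, spikes.tetrode_id,
                             circular_shift_times(spikes.times, span, shift))
        null[i] = score_fn(shifted)
    threshold = float(np.nanpercentile(null, 99))
    return ShuffleThreshold(float(observed), null, threshold,
                            bool(observed > threshold))


@dataclass
class ClassificationThresholds:
    hd_score: float = 0.4
    hd_peak_hz: float = 5.0
    distributive_ratio: float = 0.2


REQUIRED_SCORE_COLUMNS = (
    "hd_score_vp1", "hd_score_vp2", "hd_peak_vp1", "hd_peak_vp2",
    "distributive_ratio", "grid_significant", "sparsity_significant",
    "speed_significant",
)


def classify_cells(scores, thresholds: ClassificationThresholds | None = None):
    """Assign functional labels from per-cell score records.

    ``scores`` is a DataFrame with the columns in
    :data:`REQUIRED_SCORE_COLUMNS`.  A cell is a putative HD cell when its
    HD score exceeds 0.4 with a tuning-curve peak above 5 Hz in vp1 or vp2
    and its distributive ratio exceeds 0.2; grid cells are cells whose grid
    score exceeds their shuffle threshold; cells meeting both criteria are
    conjunctive grid x HD and excluded from the HD category.  Remaining
    cells fall back to speed-modulated, spatially-selective, or other.
    Returns the labels as a pandas Series aligned to ``scores``.
    """
    import pandas as pd

    th = thresholds or ClassificationThresholds()
    labels = []
    for _, row in scores.iterrows():
        vals = [row.get(c, np.nan) for c in REQUIRED_SCORE_COLUMNS]
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            labels.append("unclassifiable")
            continue
        hd_like = (
            ((row.hd_score_vp1 > th.hd_score and row.hd_peak_vp1 > th.hd_peak_hz)
             or (row.hd_score_vp2 > th.hd_score and row.hd_peak_vp2 > th.hd_peak_hz))
            and row.distributive_ratio > th.distributive_ratio
        )
        grid_like = bool(row.grid_significant)
        if hd_like and grid_like:
            labels.append("conjunctive")
        elif grid_like:
            labels.append("grid")
        elif hd_like:
            labels.append("HD")
        elif bool(row.speed_significant):
            labels.append("speed")
        elif bool(row.sparsity_significant):
            labels.append("spatial")
        else:
            labels.append("other")
    return pd.Series(labels, index=scores.index, name="label")
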