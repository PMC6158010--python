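"""Directional and spatial tuning.

HD tuning curves use 36 bins of 10 degrees.  Following the standard
occupancy-normalisation recipe, the occupancy vector is smoothed with a
circular Gaussian kernel (sd 10 deg), raw spike counts are divided by the
smoothed occupancy, and the resulting rate vector is smoothed again
(sd 10 deg).  Firing rate maps use 2 x 2 cm bins on the 70-cm platform
(35 x 35 grid) with Gaussian smoothing of sd 3 cm applied the same way.
Only periods when the animal ran faster than 3 cm/s enter either estimate;
the same speed filter is applied to curves and maps so the two estimators
stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from ._circular import resultant, wrap360
from .core import (PLATFORM_SIZE_CM, SpikeTrain, Trajectory, compute_speed,
                   interval_mask)

N_HD_BINS = 36
HD_BIN_DEG = 360.0 / N_HD_BINS
HD_SMOOTH_SD_DEG = 10.0
MAP_BIN_CM = 2.0
MAP_SMOOTH_SD_CM = 3.0
N_MAP_BINS = int(round(PLATFORM_SIZE_CM / MAP_BIN_CM))
SPEED_MIN_CMS = 3.0
MIN_OVERLAP_BINS = 20

HD_BIN_CENTERS = (np.arange(N_HD_BINS) + 0.5) * HD_BIN_DEG


@dataclass
class HDTuningCurve:
    """Occupancy-normalised, smoothed firing rate vs angle (36 x 10 deg bins)."""

    bin_centers: np.ndarray
    rate: np.ndarray          # Hz; NaN where occupancy is undefined
    occupancy: np.ndarray     # smoothed seconds per bin

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate)) if np.any(np.isfinite(self.rate)) else np.nan


@dataclass
class RateMap:
    """2-cm binned, occupancy-normalised, smoothed 2-D firing rate map.

    Axis 0 indexes x, axis 1 indexes y.  ``hd_occupancy`` holds, for each
    spatial bin, the unsmoothed time (s) spent facing each 10-deg HD bin.
    """

    bin_size: float
    rate: np.ndarray                       # Hz, NaN on invalid bins
    occupancy_s: np.ndarray                # raw seconds per bin
    occupancy_p: np.ndarray                # probability, sums to 1 on valid bins
    hd_occupancy: np.ndarray | None = None # (nx, ny, 36) seconds
    valid: np.ndarray = field(default=None)

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate)) if np.any(np.isfinite(self.rate)) else np.nan


@dataclass
class BDResult:
    """Bidirectionality summary of one tuning curve."""

    p1: float
    p2: float
    dir1: float
    dir2: float
    trough_rate: float
    bd_score: float
    is_bidirectional: bool


def _selected_samples(traj: Trajectory, speed_min: float, intervals=None):
    """Mask of tracking samples entering tuning estimates."""
    sel = traj.valid.copy()
    if speed_min is not None:
        speed = compute_speed(traj)
        sel &= np.isfinite(speed) & (speed > speed_min)
    if intervals is not None:
        sel &= interval_mask(traj.t, intervals)
    return sel


def spike_sample_indices(spike_times: np.ndarray, traj: Trajectory) -> np.ndarray:
    """Index of the nearest tracking sample for each spike."""
    idx = np.searchsorted(traj.t, spike_times)
    idx = np.clip(idx, 1, traj.t.size - 1)
    left = idx - 1
    use_left = (spike_times - traj.t[left]) < (traj.t[idx] - spike_times)
    return np.where(use_left, left, idx)


def _smooth_circular(v: np.ndarray, sd_bins: float) -> np.ndarray:
    return gaussian_filter1d(v, sigma=sd_bins, mode="wrap")


def angular_histograms(sample_angles, dt, spike_angles):
    """Raw occupancy (s) and spike-count histograms over 36 x 10-deg bins."""
    edges = np.arange(N_HD_BINS + 1) * HD_BIN_DEG
    occ = np.histogram(wrap360(sample_angles), bins=edges)[0] * dt
    cnt = np.histogram(wrap360(spike_angles), bins=edges)[0].astype(float)
    return occ, cnt


def curve_from_histograms(occ_raw: np.ndarray, cnt_raw: np.ndarray) -> HDTuningCurve:
    """Smooth occupancy, divide counts, smooth rate (all circularly)."""
    sd_bins = HD_SMOOTH_SD_DEG / HD_BIN_DEG
    occ_s = _smooth_circular(occ_raw.astype(float), sd_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_raw = np.where(occ_s > 0, cnt_raw / np.where(occ_s > 0, occ_s, 1.0), np.nan)
    defined = occ_s > 0
    if defined.all():
        rate = _smooth_circular(rate_raw, sd_bins)
    elif defined.any():
        num = _smooth_circular(np.where(defined, rate_raw, 0.0), sd_bins)
        den = _smooth_circular(defined.astype(float), sd_bins)
        rate = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        rate[~defined] = np.nan
    else:
        raise ValueError("zero total occupancy; cannot form a tuning curve")
    return HDTuningCurve(HD_BIN_CENTERS.copy(), rate, occ_s)


def _angular_tuning(sample_angles, sel, dt, spike_idx, spike_angles) -> HDTuningCurve:
    occ, cnt = angular_histograms(
        sample_angles[sel], dt, spike_angles[sel[spike_idx]]
    )
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy after filtering")
    return curve_from_histograms(occ, cnt)


def hd_tuning_curve(
    spikes: SpikeTrain,
    traj: Trajectory,
    speed_min: float = SPEED_MIN_CMS,
    intervals=None,
) -> HDTuningCurve:
    """HD tuning curve of one cell (optionally restricted to intervals)."""
    sel = _selected_samples(traj, speed_min, intervals)
    idx = spike_sample_indices(spikes.times, traj)
    return _angular_tuning(traj.hd, sel, traj.dt, idx, traj.hd[idx])


def hd_score_and_preferred(curve: HDTuningCurve) -> tuple[float, float]:
    """Mean vector length of the tuning curve and its circular mean.

    The resultant is rate-weighted over the bin centers; an all-zero (or
    all-undefined) curve has score 0 and an undefined preferred direction.
    """
    rate = np.where(np.isfinite(curve.rate), curve.rate, 0.0)
    if rate.sum() <= 0:
        return 0.0, np.nan
    score, pref = resultant(curve.bin_centers, rate)
    return float(score), pref


def firing_rate_map(
    spikes: SpikeTrain,
    traj: Trajectory,
    speed_min: float = SPEED_MIN_CMS,
    intervals=None,
    with_hd_occupancy: bool = True,
) -> RateMap:
    """2-D firing rate map (and per-bin HD occupancy for the distributive test)."""
    sel = _selected_samples(traj, speed_min, intervals)
    if not sel.any():
        raise ValueError("zero occupancy after filtering")
    dt = traj.dt
    edges = np.arange(N_MAP_BINS + 1) * MAP_BIN_CM
    x, y = traj.x[sel], traj.y[sel]
    occ = np.histogram2d(x, y, bins=[edges, edges])[0] * dt

    idx = spike_sample_indices(spikes.times, traj)
    keep = sel[idx]
    cnt = np.histogram2d(traj.x[idx[keep]], traj.y[idx[keep]], bins=[edges, edges])[0]

    sd_bins = MAP_SMOOTH_SD_CM / MAP_BIN_CM
    occ_sm = _gauss2(occ, sd_bins)
    valid = occ_sm > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_raw = np.where(valid, cnt / np.where(valid, occ_sm, 1.0), np.nan)
    num = _gauss2(np.where(valid, rate_raw, 0.0), sd_bins)
    den = _gauss2(valid.astype(float), sd_bins)
    rate = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    rate[~valid] = np.nan

    occ_p = occ / occ.sum()

    hd_occ = None
    if with_hd_occupancy:
        hd_occ = np.zeros((N_MAP_BINS, N_MAP_BINS, N_HD_BINS))
        ix = np.clip((x / MAP_BIN_CM).astype(int), 0, N_MAP_BINS - 1)
        iy = np.clip((y / MAP_BIN_CM).astype(int), 0, N_MAP_BINS - 1)
        ih = np.clip((wrap360(traj.hd[sel]) / HD_BIN_DEG).astype(int), 0, N_HD_BINS - 1)
        np.add.at(hd_occ, (ix, iy, ih), dt)

    return RateMap(MAP_BIN_CM, rate, occ, occ_p, hd_occupancy=hd_occ, valid=valid)


def _gauss2(a: np.ndarray, sd_bins: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(a, sigma=sd_bins, mode="constant")


def distributive_ratio(curve: HDTuningCurve, rate_map: RateMap):
    """Distributive-hypothesis test of HD tuning.

    The predicted tuning curve combines the cell's spatial firing rate map
    with the HD occupancy at every spatial bin:

        R_pred(theta) = sum_P R_P * T_P(theta) / sum_P T_P(theta)

    and the distributive ratio compares observed and predicted curves:

        DR = sum_theta | ln((1 + R_obs) / (1 + R_pred)) | / N

    DR near 0 means the observed HD tuning is explained by spatial
    selectivity plus biased HD sampling; cells need DR > 0.2 to count as
    genuinely head-direction tuned.  HD bins never faced anywhere on the
    map (sum_P T_P = 0) are excluded with N reduced accordingly.
    """
    if rate_map.hd_occupancy is None:
        raise ValueError("rate map lacks per-bin HD occupancy")
    R = rate_map.rate
    T = rate_map.hd_occupancy
    ok = np.isfinite(R)
    num = np.tensordot(np.where(ok, R, 0.0), np.where(ok[..., None], T, 0.0), axes=([0, 1], [0, 1]))
    den = np.where(ok[..., None], T, 0.0).sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_pred = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    predicted = HDTuningCurve(HD_BIN_CENTERS.copy(), r_pred, den)

    use = (den > 0) & np.isfinite(curve.rate)
    return predicted, dr_formula(curve.rate[use], r_pred[use])


def dr_formula(r_obs, r_pred) -> float:
    """DR = sum |ln((1+R_obs)/(1+R_pred))| / N over the supplied bins."""
    r_obs = np.asarray(r_obs, dtype=float)
    r_pred = np.asarray(r_pred, dtype=float)
    if r_obs.size == 0:
        return np.nan
    return float(np.mean(np.abs(np.log((1.0 + r_obs) / (1.0 + r_pred)))))


def egocentric_bearing_tuning(
    spikes: SpikeTrain,
    traj: Trajectory,
    landmark_xy: tuple[float, float],
    speed_min: float = SPEED_MIN_CMS,
    intervals=None,
) -> HDTuningCurve:
    """Tuning curve over the egocentric bearing of a landmark.

    For each sample the allocentric bearing phi = atan2(y1-y0, x1-x0) of
    the landmark is computed and the egocentric bearing alpha =
    wrap(phi - hd) gives the angular position of the landmark in the
    animal's field of view (0 = straight ahead).  Samples at the landmark
    position are excluded.
    """
    x1, y1 = landmark_xy
    if not (np.isfinite(x1) and np.isfinite(y1)):
        raise ValueError("landmark position must be finite")
    dx = x1 - traj.x
    dy = y1 - traj.y
    phi = wrap360(np.rad2deg(np.arctan2(dy, dx)))
    alpha = wrap360(phi - traj.hd)
    sel = _selected_samples(traj, speed_min, intervals)
    sel &= ~((dx == 0) & (dy == 0))
    idx = spike_sample_indices(spikes.times, traj)
    return _angular_tuning(alpha, sel, traj.dt, idx, alpha[idx])


def _circular_peaks(rate: np.ndarray):
    """Indices of circular local maxima (leftmost bin on plateaus)."""
    r = np.nan_to_num(rate, nan=0.0)
    left = np.roll(r, 1)
    right = np.roll(r, -1)
    return np.flatnonzero((r > left) & (r >= right))


def bd_scores(curve: HDTuningCurve, min_peak_hz: float = 2.0,
              trough_ratio: float = 1.25, bd_threshold: float = 0.2) -> BDResult:
    """Bidirectionality of one smoothed tuning curve.

    The BD score is the rate ratio of the two largest local maxima above
    ``min_peak_hz``.  The curve is bidirectional when the BD score exceeds
    ``bd_threshold``, both peaks exceed ``min_peak_hz``, and the second
    peak exceeds ``trough_ratio`` times the higher-rate of the two troughs
    separating the peaks circularly.
    """
    r = np.nan_to_num(curve.rate, nan=0.0)
    peaks = _circular_peaks(r)
    peaks = peaks[r[peaks] > min_peak_hz]
    if peaks.size < 2:
        return BDResult(curve.peak_rate if peaks.size else np.nan, np.nan,
                        np.nan, np.nan, np.nan, 0.0, False)
    order = np.argsort(r[peaks])[::-1]
    i1, i2 = peaks[order[0]], peaks[order[1]]
    p1, p2 = float(r[i1]), float(r[i2])
    lo, hi = sorted((int(i1), int(i2)))
    arc1 = r[lo + 1:hi]
    arc2 = np.concatenate([r[hi + 1:], r[:lo]])
    troughs = [float(a.min()) for a in (arc1, arc2) if a.size]
    trough_max = max(troughs) if troughs else 0.0
    score = p2 / p1
    with np.errstate(divide="ignore"):
        ratio_ok = (p2 > trough_ratio * trough_max)
    is_bd = (score > bd_threshold) and (p1 > min_peak_hz) and (p2 > min_peak_hz) and ratio_ok
    return BDResult(p1, p2, float(curve.bin_centers[i1]), float(curve.bin_centers[i2]),
                    trough_max, float(score), bool(is_bd))


def bd_analysis(curve_vp1: HDTuningCurve, curve_vp2: HDTuningCurve):
    """Per-condition bidirectionality plus the overall flag (either condition)."""
    r1 = bd_scores(curve_vp1)
    r2 = bd_scores(curve_vp2)
    return r1, r2, (r1.is_bidirectional or r2.is_bidirectional)


def map_similarity(a: RateMap, b: RateMap, min_bins: int = MIN_OVERLAP_BINS) -> float:
    """Pearson correlation over bins valid in both maps (NaN if < min_bins)."""
    if a.rate.shape != b.rate.shape:
        raise ValueError("maps must share geometry")
    ok = np.isfinite(a.rate) & np.isfinite(b.rate)
    if ok.sum() < min_bins:
        return np.nan
    va, vb = a.rate[ok], b.rate[ok]
    if va.std() == 0 or vb.std() == 0:
        return np.nan
    return float(np.corrcoef(va, vb)[0, 1])


def lagged_pearson(a: np.ndarray, b: np.ndarray,
                   min_overlap: int = MIN_OVERLAP_BINS) -> np.ndarray:
    """Pearson r between two matrices at every spatial lag.

    NaN entries are treated as invalid and excluded pairwise; lags with
    fewer than ``min_overlap`` overlapping valid bins are NaN.  The zero
    lag sits at the center of the (2*nx-1, 2*ny-1) output.
    """
    ma = np.isfinite(a).astype(float)
    mb = np.isfinite(b).astype(float)
    A = np.where(ma > 0, a, 0.0)
    B = np.where(mb > 0, b, 0.0)

    def xc(u, v):
        return fftconvolve(u, v[::-1, ::-1], mode="full")

    n = xc(ma, mb)
    sa = xc(A, mb)
    sb = xc(ma, B)
    saa = xc(A * A, mb)
    sbb = xc(ma, B * B)
    sab = xc(A, B)
    n_round = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sab - sa * sb
        var_a = np.clip(n * saa - sa * sa, 0.0, None)
        var_b = np.clip(n * sbb - sb * sb, 0.0, None)
        r = cov / np.sqrt(var_a * var_b)
    r[(n_round < min_overlap) | (var_a <= 1e-9 * np.maximum(saa, 1e-30)) |
      (var_b <= 1e-9 * np.maximum(sbb, 1e-30))] = np.nan
    return np.clip(r, -1.0, 1.0)


def spatial_crosscorrelation(a: RateMap, b: RateMap,
                             min_overlap: int = MIN_OVERLAP_BINS) -> np.ndarray:
    """2-D spatial crosscorrelation of two rate maps (Pearson r per lag)."""
    if a.rate.shape != b.rate.shape:
        raise ValueError("maps must share geometry")
    return lagged_pearson(a.rate, b.rate, min_overlap)


def preferred_hd_shift_by_quadrant(spikes, traj, speed_min=SPEED_MIN_CMS):
    """Preferred allocentric HD computed separately in each platform quadrant.

    An egocentric landmark-bearing cell shifts its apparent preferred HD
    across quadrants (parallax); an allocentric HD cell does not.  Returns
    a dict quadrant -> preferred HD (deg).
    """
    half = PLATFORM_SIZE_CM / 2.0
    out = {}
    for name, (xlo, ylo) in {"sw": (0, 0), "se": (half, 0),
                             "nw": (0, half), "ne": (half, half)}.items():
        sel = _selected_samples(traj, speed_min)
        sel &= (traj.x >= xlo) & (traj.x < xlo + half)
        sel &= (traj.y >= ylo) & (traj.y < ylo + half)
        idx = spike_sample_indices(spikes.times, traj)
        try:
            curve = _angular_tuning(traj.hd, sel, traj.dt, idx, traj.hd[idx])
        except ValueError:
            out[name] = np.nan
            continue
        out[name] = hd_score_and_preferred(curve)[1]
    return out
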