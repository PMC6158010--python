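"""Session data model, interval algebra, running speed and instantaneous rate.

A recording session binds a 50-Hz tracking trajectory (position in cm on a
70 x 70 cm platform, head direction in degrees), a trial schedule of 2-min
intervals alternating two visual-pattern conditions (vp1/vp2), one LFP trace
per tetrode, and the sorted spike trains of the recorded cells.

Time is in seconds with the session starting at 0; all intervals are
half-open [start, end).  Missing tracking samples are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

PLATFORM_SIZE_CM = 70.0
TRACKING_FS = 50.0
#: maximum tracking gap (s) bridged by linear interpolation
MAX_INTERP_GAP_S = 0.2

CONDITIONS = ("vp1", "vp2")


class ValidationError(ValueError):
    """A session component violates a structural invariant."""


@dataclass
class Trajectory:
    """Tracking samples: time (s), position (cm) and head direction (deg)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd = np.asarray(self.hd, dtype=float)
        self.validate()

    def validate(self):
        n = self.t.size
        if any(a.size != n for a in (self.x, self.y, self.hd)):
            raise ValidationError("trajectory arrays have unequal lengths")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("trajectory timestamps must be strictly increasing")
        for name, a in (("x", self.x), ("y", self.y)):
            bad = np.isfinite(a) & ((a < -1e-6) | (a > PLATFORM_SIZE_CM + 1e-6))
            if np.any(bad):
                raise ValidationError(f"trajectory {name} outside platform bounds")
        finite_hd = self.hd[np.isfinite(self.hd)]
        if finite_hd.size and (finite_hd.min() < 0 or finite_hd.max() >= 360.0):
            raise ValidationError("head direction must lie in [0, 360)")

    @property
    def valid(self) -> np.ndarray:
        """Samples with complete tracking (position and HD)."""
        return np.isfinite(self.x) & np.isfinite(self.y) & np.isfinite(self.hd)

    @property
    def dt(self) -> float:
        """Median sampling step in seconds (nominally 0.02)."""
        if self.t.size < 2:
            return 1.0 / TRACKING_FS
        return float(np.median(np.diff(self.t)))

    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def interpolate_gaps(self, max_gap_s: float = MAX_INTERP_GAP_S) -> "Trajectory":
        """Fill missing samples by linear interpolation over short gaps.

        Gaps longer than ``max_gap_s`` remain NaN and are excluded from all
        occupancy computations downstream.  HD is interpolated on the circle
        (via the unwrapped angle of the valid neighbors).
        """
        x, y, hd = self.x.copy(), self.y.copy(), self.hd.copy()
        for arr, circular in ((x, False), (y, False), (hd, True)):
            good = np.isfinite(arr)
            if good.all() or good.sum() < 2:
                continue
            tg = self.t[good]
            if circular:
                vals = np.unwrap(np.deg2rad(arr[good]))
                filled = np.interp(self.t, tg, vals)
                filled = np.mod(np.rad2deg(filled), 360.0)
            else:
                filled = np.interp(self.t, tg, arr[good])
            # only fill inside gaps short enough to trust the interpolation
            idx = np.searchsorted(tg, self.t)
            idx = np.clip(idx, 1, tg.size - 1)
            gap = tg[idx] - tg[idx - 1]
            inside = (self.t >= tg[0]) & (self.t <= tg[-1])
            fill = (~good) & inside & (gap <= max_gap_s)
            arr[fill] = filled[fill]
        return Trajectory(self.t, x, y, hd)


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit."""

    cell_id: str
    tetrode_id: str
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size >= 2 and np.any(np.diff(self.times) < 0):
            raise ValidationError(f"spike times of {self.cell_id} not sorted")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class LFPTrace:
    """One LFP channel (uV) at a fixed sampling rate."""

    tetrode_id: str
    fs: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError("LFP sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("LFP samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class TrialSchedule:
    """Time-ordered, non-overlapping trials labelled vp1/vp2."""

    starts: np.ndarray
    ends: np.ndarray
    conditions: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.validate()

    def validate(self):
        if not (self.starts.size == self.ends.size == self.conditions.size):
            raise ValidationError("schedule arrays have unequal lengths")
        if np.any(self.ends <= self.starts):
            raise ValidationError("trial end must be after start")
        if self.starts.size >= 2:
            if np.any(np.diff(self.starts) <= 0):
                raise ValidationError("trials must be time-ordered")
            if np.any(self.starts[1:] < self.ends[:-1] - 1e-9):
                raise ValidationError("trials must not overlap")
            if np.any(self.conditions[1:] == self.conditions[:-1]):
                raise ValidationError("trial conditions must alternate")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown conditions: {unknown}")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def intervals(self) -> np.ndarray:
        """(n, 2) array of [start, end) interval bounds."""
        return np.column_stack([self.starts, self.ends])

    def select(self, condition=None, trial_indices=None) -> np.ndarray:
        """Intervals of one condition and/or an explicit trial subset."""
        keep = np.ones(len(self), dtype=bool)
        if condition is not None:
            keep &= self.conditions == condition
        if trial_indices is not None:
            mask = np.zeros(len(self), dtype=bool)
            mask[np.asarray(trial_indices, dtype=int)] = True
            keep &= mask
        return self.intervals[keep]

    def trial_indices(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.conditions == condition)


@dataclass
class Session:
    """One recording: trajectory + schedule + LFP traces + spike trains."""

    trajectory: Trajectory
    schedule: TrialSchedule
    lfp: list[LFPTrace] = field(default_factory=list)
    cells: list[SpikeTrain] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t0, t1 = self.trajectory.span()
        if len(self.schedule) and (
            self.schedule.starts[0] < t0 - 1.0 or self.schedule.ends[-1] > t1 + 1.0
        ):
            raise ValidationError("schedule extends beyond the tracked span")
        for c in self.cells:
            if c.n and (c.times[0] < t0 - 1.0 or c.times[-1] > t1 + 1.0):
                raise ValidationError(f"spikes of {c.cell_id} outside session span")

    def span(self) -> tuple[float, float]:
        return self.trajectory.span()

    def cell(self, cell_id: str) -> SpikeTrain:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    def lfp_for_tetrode(self, tetrode_id: str) -> LFPTrace:
        for tr in self.lfp:
            if tr.tetrode_id == tetrode_id:
                return tr
        raise KeyError(tetrode_id)


@dataclass
class IFRTrace:
    """Instantaneous firing rate: Hz per consecutive window."""

    t: np.ndarray
    rate: np.ndarray
    kernel_sd: float
    window: float


# canonical presets: (kernel sd s, integration window s)
IFR_PRESET_BEHAVIOR = (0.2, 0.1)
IFR_PRESET_THETA = (0.005, 0.002)


def interval_mask(t, intervals) -> np.ndarray:
    """Boolean mask of samples falling inside any [start, end) interval."""
    t = np.asarray(t, dtype=float)
    mask = np.zeros(t.shape, dtype=bool)
    for s, e in np.atleast_2d(np.asarray(intervals, dtype=float)):
        mask |= (t >= s) & (t < e)
    return mask


def restrict_times(times, intervals) -> np.ndarray:
    """Spike/sample times retained inside the intervals (empty result ok)."""
    times = np.asarray(times, dtype=float)
    if np.size(intervals) == 0:
        return times[:0]
    return times[interval_mask(times, intervals)]


def intervals_duration(intervals) -> float:
    iv = np.atleast_2d(np.asarray(intervals, dtype=float))
    if iv.size == 0:
        return 0.0
    return float(np.sum(iv[:, 1] - iv[:, 0]))


def compute_speed(traj: Trajectory) -> np.ndarray:
    """Running speed (cm/s) aligned to the tracking timestamps.

    Central difference over neighboring samples, smoothed with a 3-sample
    moving mean.  Missing position samples propagate NaN.
    """
    if traj.t.size < 2:
        raise ValueError("need at least two tracking samples to compute speed")
    dx = np.gradient(traj.x, traj.t)
    dy = np.gradient(traj.y, traj.t)
    speed = np.hypot(dx, dy)
    good = np.isfinite(speed)
    if good.any():
        sm = speed.copy()
        sm[~good] = 0.0
        num = uniform_filter1d(sm, size=3, mode="nearest")
        den = uniform_filter1d(good.astype(float), size=3, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            speed = np.where(den > 0, num / den, np.nan)
        speed[~good] = np.nan
    return speed


def instantaneous_rate(
    spikes: SpikeTrain | np.ndarray,
    kernel_sd: float = IFR_PRESET_BEHAVIOR[0],
    window: float = IFR_PRESET_BEHAVIOR[1],
    span: tuple[float, float] | None = None,
) -> IFRTrace:
    """Instantaneous firing rate from 1-ms spike counts.

    Spike counts in 1-ms bins are smoothed with a Gaussian kernel
    (``kernel_sd`` seconds), integrated over consecutive windows of
    ``window`` seconds and converted to Hz.  The kernel is truncated at the
    span edges (plain convolution of a zero-padded count vector).

    Presets: behavioral time scale (sd 200 ms, window 100 ms) and theta
    time scale (sd 5 ms, window 2 ms).
    """
    if kernel_sd <= 0 or window <= 0:
        raise ValueError("kernel_sd and window must be positive")
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if span is None:
        if times.size == 0:
            raise ValueError("span required for an empty spike train")
        span = (float(times[0]), float(times[-1]))
    t0, t1 = span
    n_windows = int(np.floor((t1 - t0) / window + 1e-9))
    if n_windows < 1:
        raise ValueError("span shorter than one window")
    bin_s = 1e-3
    bins_per_window = max(1, int(round(window / bin_s)))
    n_bins = n_windows * bins_per_window
    inside = (times >= t0) & (times < t0 + n_bins * bin_s)
    counts = np.bincount(
        ((times[inside] - t0) / bin_s).astype(int), minlength=n_bins
    )[:n_bins].astype(float)
    sigma_bins = kernel_sd / bin_s
    if sigma_bins <= 50:
        smoothed = gaussian_filter1d(counts, sigma=sigma_bins, mode="constant")
    else:
        # identical zero-padded Gaussian smoothing, but O(n log n) for the
        # wide behavioral kernel on multi-hour 1-ms count vectors
        radius = int(4.0 * sigma_bins + 0.5)
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_bins) ** 2)
        k /= k.sum()
        from scipy.signal import fftconvolve
        smoothed = fftconvolve(counts, k, mode="same")
    per_window = smoothed.reshape(n_windows, bins_per_window).sum(axis=1)
    rate = per_window / window
    t = t0 + (np.arange(n_windows) + 0.5) * window
    return IFRTrace(t=t, rate=rate, kernel_sd=kernel_sd, window=window)
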