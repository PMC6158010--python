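"""Seedable generator of synthetic recording sessions with ground truth.

The generator emulates the statistical structure the analyses assume: a
foraging trajectory on a 70 x 70 cm platform with biased HD sampling, an
8-Hz theta LFP with slow amplitude/frequency jitter and 1/f noise, and
inhomogeneous-Poisson spike trains with von Mises HD tuning, optional theta
modulation, place/grid spatial fields and condition-dependent rotations or
gain changes applied instantaneously at trial boundaries.

Each generated object draws from its own RNG stream keyed by
(master seed, object index), so editing a cohort leaves the other cells'
spike trains unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (PLATFORM_SIZE_CM, TRACKING_FS, LFPTrace, Session,
                   SpikeTrain, Trajectory, TrialSchedule)

MAX_RATE_HZ = 500.0


@dataclass
class HDCellParams:
    """Generative parameters of a simulated HD cell."""

    pref_vp1: float = 90.0        # preferred HD per condition, deg
    pref_vp2: float = 90.0
    kappa: float = 2.0            # von Mises concentration
    peak_vp1: float = 20.0        # tuning-curve peak rate per condition, Hz
    peak_vp2: float = 20.0
    baseline: float = 0.5         # off-direction rate, Hz
    theta_depth: float = 0.0      # theta modulation depth in [0, 1]
    theta_phase: float = 0.0      # preferred generator phase, deg
    place_field: tuple | None = None   # (cx, cy, sd_cm, gain)
    refractory_ms: float = 2.0


@dataclass
class GridCellParams:
    """Generative parameters of a simulated grid cell."""

    spacing: float = 32.0         # cm
    orientation: float = 0.0      # deg
    phase_x: float = 0.0          # cm offset of the grid pattern
    phase_y: float = 0.0
    peak_rate: float = 15.0
    theta_depth: float = 0.6
    theta_phase: float = 0.0
    shift_vp2: tuple[float, float] = (0.0, 0.0)  # field shift in vp2, cm
    refractory_ms: float = 2.0


@dataclass
class ThetaPhase:
    """Ground-truth theta phase series of a simulated LFP."""

    fs: float
    phase_rad: np.ndarray   # unwrapped

    def at(self, times) -> np.ndarray:
        """Phase in degrees, wrapped into [0, 360)."""
        t_grid = np.arange(self.phase_rad.size) / self.fs
        return np.mod(np.rad2deg(np.interp(times, t_grid, self.phase_rad)), 360.0)


def make_schedule(n_trials: int = 40, trial_s: float = 120.0,
                  t0: float = 0.0) -> TrialSchedule:
    starts = t0 + np.arange(n_trials) * trial_s
    conditions = np.array(["vp1", "vp2"] * ((n_trials + 1) // 2))[:n_trials]
    return TrialSchedule(starts, starts + trial_s, conditions.astype(object))


def _ou(n: int, dt: float, tau: float, sd: float, rng) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck series with sd ``sd`` and time constant tau."""
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1 - a * a)
    noise = rng.normal(0, 1, n)
    noise[0] = rng.normal(0, sd) / b if b > 0 else 0.0
    return lfilter([b], [1.0, -a], noise)


def _fold(p: np.ndarray, size: float) -> np.ndarray:
    """Reflect an unbounded coordinate into [0, size] (billiard walls)."""
    m = np.mod(p, 2 * size)
    return np.where(m > size, 2 * size - m, m)


def simulate_trajectory(duration: float, seed=0, fs: float = TRACKING_FS) -> Trajectory:
    """Smoothed random-walk foraging trajectory with wall reflection.

    Velocity follows a 2-D Ornstein-Uhlenbeck process (per-component sd
    9 cm/s, time constant 1 s), giving a Rayleigh-like speed distribution
    with a median near 10 cm/s.  HD is the motion heading plus slow
    Ornstein-Uhlenbeck jitter (sd 15 deg), so HD sampling is biased by the
    path but covers all directions over a session.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs
    n = int(round(duration * fs))
    vx = _ou(n, dt, 1.0, 9.0, rng)
    vy = _ou(n, dt, 1.0, 9.0, rng)
    start = rng.uniform(10, PLATFORM_SIZE_CM - 10, size=2)
    x = _fold(start[0] + np.cumsum(vx) * dt, PLATFORM_SIZE_CM)
    y = _fold(start[1] + np.cumsum(vy) * dt, PLATFORM_SIZE_CM)
    # heading of the folded path, smoothed on the unwrapped circle
    hx = np.gradient(x, dt)
    hy = np.gradient(y, dt)
    heading = np.unwrap(np.arctan2(hy, hx))
    heading = gaussian_filter1d(heading, sigma=0.2 * fs)
    jitter = np.deg2rad(_ou(n, dt, 1.0, 15.0, rng))
    hd = np.mod(np.rad2deg(heading + jitter), 360.0)
    t = np.arange(n) * dt
    return Trajectory(t, np.clip(x, 0, PLATFORM_SIZE_CM),
                      np.clip(y, 0, PLATFORM_SIZE_CM), hd)


def simulate_lfp(duration: float, fs: float = 1250.0, theta_freq: float = 8.0,
                 snr: float = 3.0, seed=0,
                 amplitude_uv: float = 100.0) -> tuple[LFPTrace, ThetaPhase]:
    """Theta-dominated LFP: jittered 8-Hz oscillation plus 1/f noise.

    ``snr`` is the RMS ratio of the theta component to the noise; 0 gives
    pure noise.  The ground-truth (unwrapped) phase series is returned
    alongside the trace.
    """
    if fs <= 2 * theta_freq:
        raise ValueError("sampling rate must exceed twice the theta frequency")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs
    n = int(round(duration * fs))
    freq = theta_freq + _ou(n, dt, 2.0, 0.4, rng)
    phase = np.cumsum(2 * np.pi * freq * dt)
    amp = 1.0 + 0.3 * _ou(n, dt, 2.0, 1.0, rng)
    theta = np.clip(amp, 0.2, None) * np.cos(phase)

    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, dt)
    f[0] = f[1] if n > 1 else 1.0
    pink = np.fft.irfft(spec / np.sqrt(f), n)
    pink /= max(pink.std(), 1e-12)

    if snr > 0:
        sig = theta + (theta.std() / snr) * pink
    else:
        sig = pink
    trace = LFPTrace("t1", fs, amplitude_uv * sig)
    return trace, ThetaPhase(fs, phase)


def _condition_at(times: np.ndarray, schedule: TrialSchedule) -> np.ndarray:
    """0 for vp1 (and out-of-schedule), 1 for vp2, per time point."""
    idx = np.searchsorted(schedule.starts, times, side="right") - 1
    idx = np.clip(idx, 0, len(schedule) - 1)
    in_trial = (times >= schedule.starts[idx]) & (times < schedule.ends[idx])
    is_vp2 = schedule.conditions[idx] == "vp2"
    return (in_trial & is_vp2).astype(int)


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if times.size == 0 or refractory_s <= 0:
        return times
    keep = np.empty(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        ok = (t - last) >= refractory_s
        keep[i] = ok
        if ok:
            last = t
    return times[keep]


def _inhomogeneous_poisson(rate_fn, span, lam_max, rng, refractory_s=0.0):
    """Spike times by thinning a homogeneous Poisson process at ``lam_max``."""
    if lam_max > MAX_RATE_HZ:
        raise ValueError(f"peak rate {lam_max:.1f} Hz exceeds sanity bound")
    t0, t1 = span
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    lam = rate_fn(cand)
    accept = rng.uniform(0, lam_max, n_cand) < lam
    return _thin_refractory(cand[accept], refractory_s)


class _TrajInterp:
    """Linear interpolants of a trajectory (HD on the unwrapped circle)."""

    def __init__(self, traj: Trajectory):
        self.t = traj.t
        self.x = traj.x
        self.y = traj.y
        self.hd_u = np.unwrap(np.deg2rad(traj.hd))

    def hd_at(self, times):
        return np.mod(np.rad2deg(np.interp(times, self.t, self.hd_u)), 360.0)

    def xy_at(self, times):
        return (np.interp(times, self.t, self.x),
                np.interp(times, self.t, self.y))


def simulate_hd_cell(params: HDCellParams, traj: Trajectory,
                     phase: ThetaPhase | None, schedule: TrialSchedule,
                     seed=0, cell_id: str = "hd0",
                     tetrode_id: str = "t1") -> SpikeTrain:
    """Inhomogeneous-Poisson HD cell.

    The rate is gain- and direction-switched by condition at trial
    boundaries, theta-modulated when a phase series is supplied, and
    optionally multiplied by a Gaussian place-field factor:

        lam(t) = [b + (peak_c - b) vonMises(hd; pref_c, kappa)]
                 * [1 + depth cos(phi - phi0)] * place(x, y)
    """
    rng = np.random.default_rng(seed)
    interp = _TrajInterp(traj)
    p = params

    def rate_fn(times):
        cond = _condition_at(times, schedule)
        pref = np.where(cond == 1, p.pref_vp2, p.pref_vp1)
        peak = np.where(cond == 1, p.peak_vp2, p.peak_vp1)
        hd = interp.hd_at(times)
        vm = np.exp(p.kappa * (np.cos(np.deg2rad(hd - pref)) - 1.0))
        lam = p.baseline + (peak - p.baseline) * vm
        if phase is not None and p.theta_depth > 0:
            lam = lam * (1.0 + p.theta_depth
                         * np.cos(np.deg2rad(phase.at(times) - p.theta_phase)))
        if p.place_field is not None:
            cx, cy, sd, gain = p.place_field
            x, y = interp.xy_at(times)
            lam = lam * (1.0 + gain * np.exp(-((x - cx) ** 2 + (y - cy) ** 2)
                                             / (2 * sd * sd)))
        return lam

    lam_max = max(p.baseline, p.peak_vp1, p.peak_vp2) * (1.0 + p.theta_depth)
    if p.place_field is not None:
        lam_max *= 1.0 + p.place_field[3]
    times = _inhomogeneous_poisson(rate_fn, traj.span(), lam_max, rng,
                                   p.refractory_ms * 1e-3)
    return SpikeTrain(cell_id, tetrode_id, times)


def grid_rate(x, y, params: GridCellParams, shift=(0.0, 0.0)):
    """Three-cosine hexagonal rate function, scaled to [0, peak]."""
    k = 4 * np.pi / (np.sqrt(3) * params.spacing)
    g = np.zeros_like(np.asarray(x, dtype=float))
    x0 = np.asarray(x, float) - params.phase_x - shift[0]
    y0 = np.asarray(y, float) - params.phase_y - shift[1]
    for j in range(3):
        th = np.deg2rad(params.orientation + 60.0 * j)
        g = g + np.cos(k * (np.cos(th) * x0 + np.sin(th) * y0))
    return params.peak_rate * (g / 3.0 + 0.5) / 1.5


def simulate_grid_cell(params: GridCellParams, traj: Trajectory,
                       phase: ThetaPhase | None, schedule: TrialSchedule,
                       seed=0, cell_id: str = "grid0",
                       tetrode_id: str = "t1") -> SpikeTrain:
    """Theta-modulated inhomogeneous-Poisson grid cell (optionally shifting
    its pattern by ``shift_vp2`` in the vp2 condition)."""
    rng = np.random.default_rng(seed)
    interp = _TrajInterp(traj)
    p = params

    def rate_fn(times):
        x, y = interp.xy_at(times)
        cond = _condition_at(times, schedule)
        lam1 = grid_rate(x, y, p)
        if p.shift_vp2 != (0.0, 0.0):
            lam2 = grid_rate(x, y, p, shift=p.shift_vp2)
            lam = np.where(cond == 1, lam2, lam1)
        else:
            lam = lam1
        if phase is not None and p.theta_depth > 0:
            lam = lam * (1.0 + p.theta_depth
                         * np.cos(np.deg2rad(phase.at(times) - p.theta_phase)))
        return lam

    lam_max = p.peak_rate * (1.0 + p.theta_depth)
    times = _inhomogeneous_poisson(rate_fn, traj.span(), lam_max, rng,
                                   p.refractory_ms * 1e-3)
    return SpikeTrain(cell_id, tetrode_id, times)


@dataclass
class CohortSpec:
    """Composition and condition effects of a synthetic cohort.

    Theta-rhythmic HD cells rotate coherently by ``coherent_rotation_deg``
    in vp2; non-rhythmic HD cells are landmark-driven, each with an
    independent random rotation (magnitude drawn from
    ``independent_rotation_range``) and rate gain in vp2.
    """

    n_rhythmic_hd: int = 6
    n_nonrhythmic_hd: int = 6
    n_grid: int = 4
    n_untuned: int = 4
    n_trials: int = 40
    trial_s: float = 120.0
    kappa: float = 2.0
    peak_rate: float = 20.0
    baseline: float = 0.5
    theta_depth_rhythmic: float = 0.8
    coherent_rotation_deg: float = 30.0
    independent_rotation_range: tuple[float, float] = (45.0, 135.0)
    independent_gain_range: tuple[float, float] = (0.4, 1.0)
    untuned_rate_range: tuple[float, float] = (2.0, 8.0)
    grid_spacing_range: tuple[float, float] = (28.0, 40.0)
    lfp_fs: float = 1250.0
    lfp_snr: float = 3.0

    @property
    def duration(self) -> float:
        return self.n_trials * self.trial_s

    def validate(self):
        if self.n_trials < 2 or self.trial_s <= 0:
            raise ValueError("cohort needs at least two trials of positive length")
        if not 0 <= self.theta_depth_rhythmic <= 1:
            raise ValueError("theta depth must lie in [0, 1]")
        if min(self.n_rhythmic_hd, self.n_nonrhythmic_hd,
               self.n_grid, self.n_untuned) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class GroundTruth:
    """Generative record serialized alongside every synthetic session."""

    seed: int
    coherence_mode: str
    cells: dict = field(default_factory=dict)   # cell_id -> descriptor

    def to_dict(self) -> dict:
        return {"seed": self.seed, "coherence_mode": self.coherence_mode,
                "cells": self.cells}


def build_synthetic_session(spec: CohortSpec | None = None,
                            seed: int = 0) -> tuple[Session, GroundTruth]:
    """Full synthetic session: trajectory, LFP, schedule and mixed cohort.

    Theta-rhythmic HD cells share one coherent vp2 rotation; non-rhythmic
    HD cells rotate/gain-change independently; grid and untuned cells are
    condition-independent.  The ground truth of every cell is returned and
    also stored in ``session.meta["ground_truth"]``.
    """
    spec = spec or CohortSpec()
    spec.validate()
    master = np.random.SeedSequence(seed)
    streams = master.spawn(4 + spec.n_rhythmic_hd + spec.n_nonrhythmic_hd
                           + spec.n_grid + spec.n_untuned)
    schedule = make_schedule(spec.n_trials, spec.trial_s)
    traj = simulate_trajectory(spec.duration, seed=streams[0])
    lfp, phase = simulate_lfp(spec.duration, fs=spec.lfp_fs,
                              snr=spec.lfp_snr, seed=streams[1])
    assign_rng = np.random.default_rng(streams[2])

    truth = GroundTruth(seed=seed, coherence_mode="rhythmic-coherent")
    cells = []
    stream_i = 4

    for i in range(spec.n_rhythmic_hd):
        rng = np.random.default_rng(streams[stream_i]); stream_i += 1
        pref = assign_rng.uniform(0, 360)
        params = HDCellParams(
            pref_vp1=pref,
            pref_vp2=np.mod(pref + spec.coherent_rotation_deg, 360.0),
            kappa=spec.kappa, peak_vp1=spec.peak_rate, peak_vp2=spec.peak_rate,
            baseline=spec.baseline, theta_depth=spec.theta_depth_rhythmic,
            theta_phase=assign_rng.uniform(0, 360))
        cid = f"tr_hd_{i:02d}"
        cells.append(simulate_hd_cell(params, traj, phase, schedule,
                                      seed=rng, cell_id=cid,
                                      tetrode_id=f"t{1 + i % 4}"))
        truth.cells[cid] = {"kind": "hd_rhythmic", "params": asdict(params),
                            "rotation_deg": spec.coherent_rotation_deg,
                            "gain_ratio": 1.0}

    for i in range(spec.n_nonrhythmic_hd):
        rng = np.random.default_rng(streams[stream_i]); stream_i += 1
        pref = assign_rng.uniform(0, 360)
        rot = (assign_rng.uniform(*spec.independent_rotation_range)
               * assign_rng.choice([-1.0, 1.0]))
        gain = assign_rng.uniform(*spec.independent_gain_range)
        params = HDCellParams(
            pref_vp1=pref, pref_vp2=np.mod(pref + rot, 360.0),
            kappa=spec.kappa, peak_vp1=spec.peak_rate,
            peak_vp2=spec.peak_rate * gain, baseline=spec.baseline,
            theta_depth=0.0)
        cid = f"nr_hd_{i:02d}"
        cells.append(simulate_hd_cell(params, traj, phase, schedule,
                                      seed=rng, cell_id=cid,
                                      tetrode_id=f"t{5 + i % 4}"))
        truth.cells[cid] = {"kind": "hd_nonrhythmic", "params": asdict(params),
                            "rotation_deg": float(rot), "gain_ratio": float(gain)}

    for i in range(spec.n_grid):
        rng = np.random.default_rng(streams[stream_i]); stream_i += 1
        params = GridCellParams(
            spacing=assign_rng.uniform(*spec.grid_spacing_range),
            orientation=assign_rng.uniform(0, 60),
            phase_x=assign_rng.uniform(0, 40),
            phase_y=assign_rng.uniform(0, 40),
            peak_rate=15.0, theta_depth=0.6,
            theta_phase=assign_rng.uniform(0, 360))
        cid = f"grid_{i:02d}"
        cells.append(simulate_grid_cell(params, traj, phase, schedule,
                                        seed=rng, cell_id=cid,
                                        tetrode_id=f"t{1 + i % 4}"))
        truth.cells[cid] = {"kind": "grid", "params": asdict(params),
                            "rotation_deg": 0.0, "gain_ratio": 1.0}

    for i in range(spec.n_untuned):
        rng = np.random.default_rng(streams[stream_i]); stream_i += 1
        rate = assign_rng.uniform(*spec.untuned_rate_range)
        params = HDCellParams(pref_vp1=0.0, pref_vp2=0.0, kappa=0.0,
                              peak_vp1=rate, peak_vp2=rate, baseline=rate,
                              theta_depth=0.0)
        cid = f"untuned_{i:02d}"
        cells.append(simulate_hd_cell(params, traj, None, schedule,
                                      seed=rng, cell_id=cid,
                                      tetrode_id=f"t{5 + i % 4}"))
        truth.cells[cid] = {"kind": "untuned", "params": asdict(params),
                            "rotation_deg": 0.0, "gain_ratio": 1.0}

    session = Session(traj, schedule, lfp=[lfp], cells=cells,
                      meta={"synthetic": True, "seed": int(seed),
                            "ground_truth": truth.to_dict()})
    return session, truth
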