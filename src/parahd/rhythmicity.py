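"""Theta rhythmicity of spike trains, LFP theta cycles, phase locking,
theta-cycle skipping and cluster quality.

The theta-rhythmicity index of a cell is computed from the power spectrum of
its instantaneous firing rate (Gaussian kernel sd 5 ms, 2 ms windows, i.e. a
500 Hz rate series; Welch spectrum with 4-s Hann segments, 50% overlap).
Spectral density estimates are scaled by their frequency, and

    theta index = (theta - baseline) / (theta + baseline)

with theta the mean scaled power at 6-10 Hz and baseline the mean over the
two flanking bands 3-5 and 11-13 Hz (an alternative 1.5-3 Hz lower band is
available to reduce the influence of subharmonic theta).  The population of
per-cell indices is classified by a 1-D Gaussian mixture fit with EM, the
component count chosen by BIC.

LFP theta epochs are windows (500 ms) where the 6-10 Hz / 2-4 Hz RMS power
ratio exceeds two; cycle boundaries are positive-to-negative zero crossings
of the 5-14 Hz band-passed signal (phase 0/360).  With this convention the
theta trough falls near 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._circular import rayleigh_test, resultant
from .core import IFR_PRESET_THETA, LFPTrace, SpikeTrain, instantaneous_rate

THETA_BAND = (6.0, 10.0)
BASELINE_BANDS = ((3.0, 5.0), (11.0, 13.0))
BASELINE_BANDS_ALT = ((1.5, 3.0), (11.0, 13.0))
DELTA_BAND = (2.0, 4.0)
CYCLE_BAND = (5.0, 14.0)


@dataclass
class RateSpectrum:
    freq: np.ndarray
    power: np.ndarray            # spectral density x frequency
    theta_power: float
    baseline_power: float
    n_spikes: int


@dataclass
class ThetaIndexMixture:
    indices: np.ndarray
    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    df: int
    bic: float
    threshold: float             # NaN unless k == 2
    labels: np.ndarray           # 0 = lowest-mean component
    bic_by_k: dict


@dataclass
class ThetaCycles:
    epochs: np.ndarray           # (n, 2) seconds
    boundaries: np.ndarray       # cycle-boundary times (s)
    epoch_index: np.ndarray      # epoch id per boundary

    @property
    def cycles(self) -> np.ndarray:
        """(m, 2) consecutive boundary pairs within the same epoch."""
        if self.boundaries.size < 2:
            return np.empty((0, 2))
        same = self.epoch_index[1:] == self.epoch_index[:-1]
        return np.column_stack([self.boundaries[:-1][same], self.boundaries[1:][same]])


@dataclass
class PhaseLocking:
    phases: np.ndarray           # degrees per in-cycle spike
    mvl: float
    preferred_phase: float
    rayleigh_stat: float
    rayleigh_p: float


@dataclass
class AutocorrHist:
    lags: np.ndarray             # bin centers, ms
    counts: np.ndarray
    bin_width: float             # ms
    window: float                # ms


def rate_power_spectrum(
    spikes: SpikeTrain | np.ndarray,
    span: tuple[float, float],
    min_spikes: int = 100,
    segment_s: float = 4.0,
) -> RateSpectrum | None:
    """Frequency-scaled Welch spectrum of the theta-time-scale IFR.

    Returns None (flagged undefined) when the train has fewer than
    ``min_spikes`` spikes in the span.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if span[1] - span[0] < 60.0:
        raise ValueError("span must be at least 60 s")
    n_in = int(np.sum((times >= span[0]) & (times < span[1])))
    if n_in < min_spikes:
        return None
    sd, window = IFR_PRESET_THETA
    ifr = instantaneous_rate(times, kernel_sd=sd, window=window, span=span)
    fs = 1.0 / window
    nperseg = int(round(segment_s * fs))
    freq, pxx = signal.welch(ifr.rate, fs=fs, window="hann",
                             nperseg=nperseg, noverlap=nperseg // 2)
    power = pxx * freq
    theta = _band_mean(freq, power, [THETA_BAND])
    base = _band_mean(freq, power, BASELINE_BANDS)
    return RateSpectrum(freq, power, theta, base, n_in)


def _band_mean(freq, power, bands) -> float:
    mask = np.zeros(freq.shape, dtype=bool)
    for lo, hi in bands:
        mask |= (freq >= lo) & (freq <= hi)
    return float(power[mask].mean()) if mask.any() else np.nan


def theta_index(spec: RateSpectrum, alt_baseline: bool = False) -> float:
    """Normalised theta-band excess of the rate spectrum, in [-1, 1]."""
    if spec is None:
        return np.nan
    theta = spec.theta_power
    base = (_band_mean(spec.freq, spec.power, BASELINE_BANDS_ALT)
            if alt_baseline else spec.baseline_power)
    if theta + base == 0:
        return np.nan
    return float((theta - base) / (theta + base))


def fit_theta_index_mixture(indices, k_max: int = 4, seed: int = 0) -> ThetaIndexMixture:
    """1-D Gaussian mixture (unequal variances) fit by EM, k chosen by BIC.

    BIC follows the higher-is-better convention 2*loglik - df*ln(n).  When
    the chosen model has two components, the reported threshold is the
    index at which the posterior responsibilities of the two components are
    equal (between the component means).
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(indices, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 indices to fit a mixture")
    X = x.reshape(-1, 1)
    fits = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=10, random_state=seed, tol=1e-8,
                             max_iter=2000)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        if not gm.converged_:
            continue  # overparameterised k can fail to converge; skip it
        loglik = float(gm.score(X) * x.size)
        df = 3 * k - 1
        bic = 2.0 * loglik - df * np.log(x.size)
        fits[k] = (gm, loglik, df, bic)
    if not fits:
        raise RuntimeError("EM did not converge for any component count")
    best_k = max(fits, key=lambda k: fits[k][3])
    gm, loglik, df, bic = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(-1)[order])
    weights = gm.weights_[order]
    post = gm.predict_proba(X)[:, order]
    labels = np.argmax(post, axis=1)

    threshold = np.nan
    if best_k == 2:
        from scipy.optimize import brentq

        def diff(v):
            p = gm.predict_proba(np.array([[v]]))[0, order]
            return p[0] - p[1]

        lo, hi = means
        if diff(lo) > 0 > diff(hi):
            threshold = float(brentq(diff, lo, hi, xtol=1e-10))
    return ThetaIndexMixture(x, int(best_k), means, sds, weights, loglik, df,
                             float(bic), threshold, labels,
                             {k: fits[k][3] for k in fits})


def _bandpass(x, fs, band, order=4):
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_theta(lfp: LFPTrace, ratio_threshold: float = 2.0,
                 window_s: float = 0.5) -> ThetaCycles:
    """Theta epochs (theta/delta RMS ratio > 2) and cycle boundaries."""
    if lfp.fs < 250:
        raise ValueError("LFP sampling rate must be at least 250 Hz")
    if lfp.duration < 1.0:
        raise ValueError("LFP trace shorter than 1 s")
    x = lfp.samples
    fs = lfp.fs
    theta_f = _bandpass(x, fs, THETA_BAND)
    delta_f = _bandpass(x, fs, DELTA_BAND)
    n_win = int(x.size // int(window_s * fs))
    wlen = int(window_s * fs)

    def rms(v):
        v = v[: n_win * wlen].reshape(n_win, wlen)
        return np.sqrt(np.mean(v * v, axis=1))

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rms(theta_f) / rms(delta_f)
    is_theta = ratio > ratio_threshold
    epochs = []
    i = 0
    while i < n_win:
        if is_theta[i]:
            j = i
            while j + 1 < n_win and is_theta[j + 1]:
                j += 1
            epochs.append((i * window_s, (j + 1) * window_s))
            i = j + 1
        else:
            i += 1
    epochs = np.asarray(epochs, dtype=float).reshape(-1, 2)

    cyc = _bandpass(x, fs, CYCLE_BAND)
    down = np.flatnonzero((cyc[:-1] >= 0) & (cyc[1:] < 0))
    # linear interpolation of the crossing time between samples
    frac = cyc[down] / (cyc[down] - cyc[down + 1])
    t_cross = (down + frac) / fs

    boundaries, epoch_idx = [], []
    for e, (s, t) in enumerate(epochs):
        inside = t_cross[(t_cross >= s) & (t_cross < t)]
        boundaries.append(inside)
        epoch_idx.append(np.full(inside.size, e))
    boundaries = np.concatenate(boundaries) if boundaries else np.empty(0)
    epoch_idx = np.concatenate(epoch_idx) if epoch_idx else np.empty(0, dtype=int)
    return ThetaCycles(epochs, boundaries, epoch_idx.astype(int))


def lfp_phase(cycles: ThetaCycles, t: np.ndarray) -> np.ndarray:
    """Theta phase (deg) at arbitrary times by linear interpolation within
    cycle boundaries; NaN outside cycles."""
    t = np.asarray(t, dtype=float)
    phase = np.full(t.shape, np.nan)
    b = cycles.boundaries
    if b.size < 2:
        return phase
    idx = np.searchsorted(b, t) - 1
    ok = (idx >= 0) & (idx < b.size - 1)
    same_epoch = np.zeros(t.shape, dtype=bool)
    same_epoch[ok] = cycles.epoch_index[idx[ok]] == cycles.epoch_index[idx[ok] + 1]
    ok &= same_epoch
    i = idx[ok]
    phase[ok] = 360.0 * (t[ok] - b[i]) / (b[i + 1] - b[i])
    return phase


def spike_phase_locking(spikes: SpikeTrain, cycles: ThetaCycles,
                        min_spikes: int = 30) -> PhaseLocking:
    """Per-spike theta phases, their resultant and the Rayleigh test."""
    phases = lfp_phase(cycles, spikes.times)
    phases = phases[np.isfinite(phases)]
    if phases.size < min_spikes:
        raise ValueError("too few spikes inside theta cycles")
    mvl, pref = resultant(phases)
    z, p = rayleigh_test(phases)
    return PhaseLocking(phases, float(mvl), pref, z, p)


def spike_time_autocorrelation(spikes: SpikeTrain | np.ndarray,
                               window_ms: float = 300.0,
                               bin_ms: float = 2.0) -> AutocorrHist:
    """Histogram of positive spike-pair lags up to ``window_ms``."""
    t = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if t.size < 2:
        raise ValueError("need at least two spikes")
    win = window_ms * 1e-3
    edges = np.arange(0.0, window_ms + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1)
    k = 1
    while k < t.size:
        d = t[k:] - t[:-k]
        m = d <= win
        if not m.any():
            break
        counts += np.histogram(d[m] * 1e3, bins=edges)[0]
        k += 1
    lags = (edges[:-1] + edges[1:]) / 2.0
    return AutocorrHist(lags, counts, bin_ms, window_ms)


def theta_skipping_index(ac: AutocorrHist, threshold: float = 0.1):
    """Cycle-skipping index (p2 - p1)/max(p1, p2) with p1 the peak count at
    100-150 ms and p2 at 200-300 ms; skipping when index > threshold."""
    in1 = (ac.lags >= 100.0) & (ac.lags <= 150.0)
    in2 = (ac.lags >= 200.0) & (ac.lags <= 300.0)
    if not (in1.any() and in2.any()):
        raise ValueError("autocorrelation must cover 100-300 ms")
    p1 = float(ac.counts[in1].max())
    p2 = float(ac.counts[in2].max())
    if p1 == 0 and p2 == 0:
        return np.nan, False
    index = (p2 - p1) / max(p1, p2)
    return float(index), bool(index > threshold)


def refractory_ratio(ac: AutocorrHist, discard_above: float = 0.125):
    """Cluster-quality ratio: mean counts at 0-1.5 ms over the maximum count
    in any 5-25 ms bin (0.5 ms bins); clusters above 0.125 are discarded."""
    if ac.bin_width > 0.5 + 1e-9 or ac.window < 25:
        raise ValueError("refractory ratio needs 0.5 ms bins over 0-25 ms")
    early = ac.lags < 1.5
    late = (ac.lags >= 5.0) & (ac.lags <= 25.0)
    denom = ac.counts[late].max()
    if denom == 0:
        return np.nan, False
    ratio = float(ac.counts[early].mean() / denom)
    return ratio, bool(ratio > discard_above)


def isolation_distance(cluster_features: np.ndarray,
                       noise_features: np.ndarray) -> float:
    """Mahalanobis distance (squared) of the n-th closest non-member spike,
    n = cluster size, using the cluster's own covariance."""
    c = np.asarray(cluster_features, dtype=float)
    o = np.asarray(noise_features, dtype=float)
    n = c.shape[0]
    if o.shape[0] < n:
        return np.nan
    mean = c.mean(axis=0)
    cov = np.cov(c, rowvar=False)
    inv = np.linalg.pinv(np.atleast_2d(cov))
    d = o - mean
    md2 = np.einsum("ij,jk,ik->i", d, inv, d)
    return float(np.sort(md2)[n - 1])
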