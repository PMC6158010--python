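"""Pairwise firing associations, reorganization scores and theta synchrony.

Attractor dynamics predict that the difference in preferred direction (and
more generally the firing association) of two simultaneously recorded cells
is invariant to sensory manipulations.  The between-condition reorganization
score of a pair (i, j) quantifies violations of this prediction:

    |(PrefHD_j,vp1 - PrefHD_i,vp1) - (PrefHD_j,vp2 - PrefHD_i,vp2)|

(circular, reported in [0, 180]); the analogous construction on two
mutually exclusive subsets of vp1 trials (odd vs even) gives the
within-condition control.  HD-score reorganization replaces the preferred
direction by the mean vector length; IFR reorganization is the absolute
between-condition change of the pair's instantaneous-firing-rate
correlation.

Theta synchrony of a pair is the normalised 6-10 Hz Morlet wavelet power of
the z-scored spike-time crosscorrelation near zero lag (|lag| <= 25 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ._circular import circ_diff, circ_dist
from .core import IFRTrace, SpikeTrain, TrialSchedule, interval_mask
from .landmark import MIN_SCORE_FOR_PREF, TrialSummaries
from .tuning import RateMap, hd_score_and_preferred, map_similarity

THETA_SYNCHRONY_THRESHOLD = 0.2


@dataclass
class ReorganizationResult:
    pair: tuple[str, str]
    pref: dict          # subset -> (pref_i, pref_j)
    score: dict         # subset -> (score_i, score_j)
    between_pref: float
    within_pref: float
    between_score: float
    within_score: float
    between_ifr: float
    within_ifr: float


@dataclass
class ThetaSynchrony:
    lags_ms: np.ndarray
    z: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    score: float
    synchrony_class: str    # "LTS" or "HTS"


def ifr_association(a: IFRTrace, b: IFRTrace, intervals=None) -> float:
    """Pearson correlation of two cells' IFR vectors (optionally only over
    windows whose centers fall inside the given intervals)."""
    if a.t.size != b.t.size or abs(a.window - b.window) > 1e-12:
        raise ValueError("IFR traces must share their time base")
    ok = np.ones(a.t.size, dtype=bool)
    if intervals is not None:
        ok = interval_mask(a.t, intervals)
    if ok.sum() < 100:
        raise ValueError("need at least 100 common IFR windows")
    va, vb = a.rate[ok], b.rate[ok]
    if va.std() == 0 or vb.std() == 0:
        return np.nan
    return float(np.corrcoef(va, vb)[0, 1])


def _subsets(schedule: TrialSchedule):
    """Trial-index subsets: vp1, vp2, and odd/even vp1 halves."""
    i1 = schedule.trial_indices("vp1")
    i2 = schedule.trial_indices("vp2")
    return {"vp1": i1, "vp2": i2, "vp1.1": i1[0::2], "vp1.2": i1[1::2]}


def _pref_and_score(sm: TrialSummaries, idx):
    s, p = hd_score_and_preferred(sm.curve(idx))
    if s < MIN_SCORE_FOR_PREF:
        p = np.nan
    return p, s


def reorganization_scores(
    sm_i: TrialSummaries,
    sm_j: TrialSummaries,
    schedule: TrialSchedule,
    ifr_i: IFRTrace | None = None,
    ifr_j: IFRTrace | None = None,
    pair=("i", "j"),
) -> ReorganizationResult:
    """Between- and within-condition reorganization of one cell pair.

    The preferred-HD score is computed circularly; any sub-condition with an
    undefined preferred direction makes the corresponding score NaN.  IFR
    scores are NaN unless both IFR traces are supplied.
    """
    subs = _subsets(schedule)
    pref, score = {}, {}
    for name, idx in subs.items():
        pi, si = _pref_and_score(sm_i, idx)
        pj, sj = _pref_and_score(sm_j, idx)
        pref[name] = (pi, pj)
        score[name] = (si, sj)

    def pref_reorg(a, b):
        (pia, pja), (pib, pjb) = pref[a], pref[b]
        if any(not np.isfinite(v) for v in (pia, pja, pib, pjb)):
            return np.nan
        return float(circ_dist(circ_diff(pja, pia), circ_diff(pjb, pib)))

    def score_reorg(a, b):
        (sia, sja), (sib, sjb) = score[a], score[b]
        return float(abs((sja - sia) - (sjb - sib)))

    between_ifr = within_ifr = np.nan
    if ifr_i is not None and ifr_j is not None:
        r = {name: ifr_association(ifr_i, ifr_j, schedule.select(trial_indices=idx))
             for name, idx in subs.items()}
        between_ifr = abs(r["vp1"] - r["vp2"])
        within_ifr = abs(r["vp1.1"] - r["vp1.2"])

    return ReorganizationResult(
        pair, pref, score,
        between_pref=pref_reorg("vp1", "vp2"),
        within_pref=pref_reorg("vp1.1", "vp1.2"),
        between_score=score_reorg("vp1", "vp2"),
        within_score=score_reorg("vp1.1", "vp1.2"),
        between_ifr=float(between_ifr),
        within_ifr=float(within_ifr),
    )


def _pair_lag_histogram(a: np.ndarray, b: np.ndarray, window_ms: float,
                        bin_ms: float):
    win = window_ms * 1e-3
    half = bin_ms * 1e-3 / 2.0
    lo = np.searchsorted(b, a - win - half)
    hi = np.searchsorted(b, a + win + half)
    lens = hi - lo
    total = int(lens.sum())
    edges = np.arange(-window_ms - bin_ms / 2, window_ms + bin_ms, bin_ms)
    if total == 0:
        return (edges[:-1] + edges[1:]) / 2, np.zeros(edges.size - 1)
    starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
    ids = np.arange(total) - np.repeat(starts, lens) + np.repeat(lo, lens)
    diffs = (b[ids] - np.repeat(a, lens)) * 1e3
    counts = np.histogram(diffs, bins=edges)[0].astype(float)
    return (edges[:-1] + edges[1:]) / 2, counts


def crosscorr_z(a: SpikeTrain, b: SpikeTrain, window_ms: float = 300.0,
                bin_ms: float = 2.0):
    """Z-scored spike-time crosscorrelation (counts of b-spikes at lags
    -300..300 ms around each a-spike, 2 ms bins, z-scored across bins)."""
    if a.n == 0 or b.n == 0:
        raise ValueError("both spike trains must be non-empty")
    lags, counts = _pair_lag_histogram(a.times, b.times, window_ms, bin_ms)
    sd = counts.std()
    z = (counts - counts.mean()) / sd if sd > 0 else np.zeros_like(counts)
    return lags, z


def theta_synchrony(lags_ms: np.ndarray, z: np.ndarray,
                    theta_band=(6.0, 10.0), lag_window_ms: float = 25.0,
                    threshold: float = THETA_SYNCHRONY_THRESHOLD) -> ThetaSynchrony:
    """Normalised theta-band wavelet power of a z-scored crosscorrelation.

    A complex Morlet wavelet (omega0 = 6) is evaluated on 30 log-spaced
    frequencies over 2-20 Hz with the lag axis as time.  The raw power at
    each scale is normalised by the wavelet's squared L2 norm at that scale
    (obtained from its impulse response), which equals the expected power
    of a unit-variance white z vector.  Since z-scoring already fixes the
    crosscorrelation to unit variance, a pair with no theta structure has
    normalised power ~1 everywhere; the score is the mean normalised power
    at 6-10 Hz within |lag| <= 25 ms minus this white baseline (clipped at
    zero), so untuned pairs score near 0 and theta-synchronous pairs score
    far above the classification threshold.
    """
    import pywt

    dt = (lags_ms[1] - lags_ms[0]) * 1e-3
    freqs = np.logspace(np.log10(2.0), np.log10(20.0), 30)
    wavelet = "cmor2.0-0.9549"   # bandwidth 2, center freq 6/(2*pi): Morlet omega0=6
    fc = pywt.central_frequency(wavelet)
    scales = fc / (freqs * dt)
    coef, eff_freqs = pywt.cwt(z, scales, wavelet, sampling_period=dt)
    power = np.abs(coef) ** 2
    if power.mean() == 0:
        return ThetaSynchrony(lags_ms, z, eff_freqs, power, 0.0, "LTS")
    # expected white-noise power per scale = squared L2 norm of the
    # discretised wavelet, measured from its impulse response
    impulse = np.zeros(z.size)
    impulse[z.size // 2] = 1.0
    coef_imp, _ = pywt.cwt(impulse, scales, wavelet, sampling_period=dt)
    white_level = np.sum(np.abs(coef_imp) ** 2, axis=1)
    norm_power = power / white_level[:, None]
    frow = (eff_freqs >= theta_band[0]) & (eff_freqs <= theta_band[1])
    ccol = np.abs(lags_ms) <= lag_window_ms
    score = float(max(norm_power[np.ix_(frow, ccol)].mean() - 1.0, 0.0))
    power = norm_power
    return ThetaSynchrony(lags_ms, z, eff_freqs, power, score,
                          "HTS" if score > threshold else "LTS")


def derive_synchrony_threshold(scores, seed: int = 0) -> float:
    """Valley of a two-component Gaussian mixture fit to synchrony scores
    (falls back to the default threshold if the fit degenerates)."""
    from .rhythmicity import fit_theta_index_mixture

    try:
        fit = fit_theta_index_mixture(scores, k_max=2, seed=seed)
    except (ValueError, RuntimeError):
        return THETA_SYNCHRONY_THRESHOLD
    if fit.k == 2 and np.isfinite(fit.threshold):
        return float(fit.threshold)
    return THETA_SYNCHRONY_THRESHOLD


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int):
    """Compare two independent correlations via the Fisher transform:

        Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))

    Returns (Z, two-sided p).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    if min(n1, n2) <= 3:
        raise ValueError("n must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class GridPairCoherence:
    pair: tuple[str, str]
    map_sim: dict              # subset -> pairwise map similarity
    ifr: dict                  # subset -> IFR association
    between_map: float
    within_map: float
    between_ifr: float
    within_ifr: float


def grid_pair_coherence(
    maps_i: dict[str, RateMap],
    maps_j: dict[str, RateMap],
    ifr_i: IFRTrace,
    ifr_j: IFRTrace,
    schedule: TrialSchedule,
    pair=("i", "j"),
) -> GridPairCoherence:
    """Between/within reorganization of IFR association and pairwise map
    similarity for a grid-cell pair.  ``maps_i``/``maps_j`` map the subset
    names vp1, vp2, vp1.1, vp1.2 to per-subset rate maps of each cell."""
    subs = _subsets(schedule)
    sim = {name: map_similarity(maps_i[name], maps_j[name]) for name in subs}
    r = {name: ifr_association(ifr_i, ifr_j, schedule.select(trial_indices=idx))
         for name, idx in subs.items()}
    return GridPairCoherence(
        pair, sim, r,
        between_map=abs(sim["vp1"] - sim["vp2"]),
        within_map=abs(sim["vp1.1"] - sim["vp1.2"]),
        between_ifr=abs(r["vp1"] - r["vp2"]),
        within_ifr=abs(r["vp1.1"] - r["vp1.2"]),
    )
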