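# Methods

This note documents the estimators, their numerical choices, and what the
synthetic-data generator does and does not emulate.

## Data model

A session binds a 50-Hz tracking trajectory (x, y in cm on a 70 × 70 cm
platform, head direction in degrees), a schedule of 2-min trials
alternating two visual-pattern conditions (vp1/vp2; forty trials in a full
80-min session), one LFP channel per tetrode, and sorted spike trains.
Time is in seconds from session start; intervals are half-open
[start, end).  Missing tracking samples (LED dropouts) are linearly
interpolated when the gap is at most 200 ms — the interpolation policy is
our choice; longer gaps stay missing and contribute no occupancy.

Running speed is a central difference of position over neighboring
samples, smoothed with a 3-sample moving mean: robust at 50 Hz without
phase lag.  All tuning estimates use only samples faster than 3 cm/s; we
apply this filter to HD tuning curves as well as rate maps so the two
estimators see the same behavioral epochs.

## Instantaneous firing rate (IFR)

Spike counts in 1-ms bins are smoothed with a Gaussian kernel and
integrated over consecutive windows, in two presets: sd 200 ms with 100-ms
windows (behavioral time scale: speed scores, IFR associations) and sd
5 ms with 2-ms windows (theta time scale: rate spectra).  The kernel is
truncated at the span edges without renormalisation, i.e. plain
convolution of a zero-padded count vector.  For the wide kernel the
convolution runs via FFT; this is numerically identical (≲1e-10) to the
direct filter.  The per-window Gaussian mass can also be accumulated
directly from spike times (an O(spikes) path used inside shuffle loops);
it agrees with the binned definition to within the 1-ms quantisation.

## Directional and spatial tuning

HD tuning curves use 36 bins of 10°.  The occupancy vector is smoothed
with a circular Gaussian (sd 10° = 1 bin), raw spike counts are divided by
the smoothed occupancy, and the rate vector is smoothed again (sd 10°) —
occupancy first, division second, rate smoothing last.  Bins whose
smoothed occupancy is zero are undefined (NaN) and excluded pairwise from
every downstream comparison, with N adjusted.  Spikes inherit the
trajectory sample nearest in time.  The HD score is the rate-weighted mean
resultant length over bin centers; the preferred direction is the circular
mean.  An all-zero curve has score 0 and an undefined preferred direction;
preferred directions of curves with score < 0.05 are treated as undefined
in change and pair statistics.

Rate maps use 2-cm bins (35 × 35), Gaussian smoothing of sd 3 cm applied
in the same order, zero-padded at the platform edge.  Raw (unsmoothed)
occupancy seconds are kept alongside, both for exact occupancy accounting
and as the probability weights p_i of the sparsity score.

The distributive ratio guards against HD tuning that is an artifact of
spatial selectivity plus biased HD sampling.  The per-bin HD occupancy
T_P(θ) is accumulated unsmoothed; the predicted curve is
R_pred(θ) = Σ_P R_P T_P(θ) / Σ_P T_P(θ) over valid map bins, and
DR = Σ_θ |ln((1+R_obs)/(1+R_pred))| / N.  HD bins never faced anywhere on
the map are excluded with N reduced.  Cells need DR > 0.2 to count as HD
cells.

Egocentric landmark bearing: α = wrap(φ − hd) with φ the allocentric
bearing of the landmark from the animal's position; tuning curves over α
are built exactly like HD curves.  Angles are degrees, counterclockwise
positive, wrapped into [0, 360); absolute circular differences are
reported in [0, 180].

Bidirectionality: local maxima of the smoothed 36-bin curve (circular
neighbors, leftmost bin on plateaus) above 2 Hz are peaks;
BD = p2/p1.  A curve is bidirectional when BD > 0.2, both peaks exceed
2 Hz, and p2 exceeds 1.25 × the higher of the two troughs separating the
peaks circularly.  Troughs are taken on the same smoothed curve the peaks
come from.

Map similarity is the Pearson correlation over bins valid in both maps
(undefined below 20 common bins).  Spatial auto/crosscorrelations compute
the Pearson r at every lag from six FFT cross-correlations of the masked
maps; lags with fewer than 20 overlapping valid bins are undefined.

## Grid, sparsity and speed scores; shuffle thresholds

Autocorrelation peaks are 4-connected components of bins > 0.1 with more
than 10 bins, located at their maximum.  The scoring annulus runs from the
edge of the component containing the zero-lag bin to the distance of the
6th-nearest non-central peak plus half a peak width (mean of
sqrt(area/π) over the selected peaks), capped at the matrix border — the
annulus construction is our deterministic reading of "up to six peaks
excluding the center".  Rotation correlations (30/60/90/120/150°) use
bilinear interpolation; bins whose rotated position leaves the valid
region are dropped.  Grid score = (r60 + r120)/2 − (r30 + r90 + r150)/3;
it is 0 to numerical precision (~1e-5, bilinear resampling) for any
rotation-invariant pattern.

Sparsity = 1 − (Σ p_i λ_i)² / Σ p_i λ_i², oriented so high values mean
high sparsity.  Speed score = Pearson r between running speed and the
behavioral-preset IFR over windows with speed in (3, 100) cm/s.

Significance thresholds for grid/sparsity/speed scores are cell-specific:
the tracking data are circularly time-shifted relative to the spike train
by a uniform shift in [20 s, T − 20 s], the score recomputed, 100 times;
the threshold is the 99th percentile of the null.  One RNG stream per cell
keyed by the master seed keeps results reproducible under cohort edits.

Cell classification: HD ⇔ (HD score > 0.4 and tuning-curve peak > 5 Hz in
vp1 or vp2) and DR > 0.2 and not grid-significant; grid ⇔ grid score
above its shuffle threshold; cells meeting both are conjunctive grid × HD
and excluded from the HD class; remaining cells fall back to
speed-modulated, spatially selective, or other.

## Theta rhythmicity

The rate spectrum is a Welch estimate (4-s Hann segments, 50% overlap —
our fixed choice; only the method itself is canonical) of the theta-preset
IFR (500 Hz series), scaled by frequency.  Theta index =
(θ − baseline)/(θ + baseline) with θ the mean scaled power at 6–10 Hz and
baseline the mean over 3–5 and 11–13 Hz; a 1.5–3 Hz lower band variant
reduces the influence of subharmonic theta.  Cells with fewer than 100
spikes have an undefined spectrum.  Note the 5-ms kernel attenuates the
upper baseline band slightly more than the theta band, so even a Poisson
train has a small positive index (~+0.02); the mixture boundary absorbs
this offset.

Theta indices of the HD-cell population are fit with 1-D Gaussian
mixtures (unequal variances) by EM for k = 1..4 (10 restarts, tolerance
1e-8; component counts whose EM fails to converge are skipped), choosing k
by BIC in the higher-is-better convention 2 logL − df log n.  When k = 2
the class boundary is the index where the two posterior responsibilities
cross between the component means.  The pipeline uses this boundary (a
config override is available) to label cells non-rhythmic vs
theta-rhythmic.

LFP theta: zero-phase 4th-order Butterworth band-passes (delta 2–4 Hz,
theta 6–10 Hz, cycles 5–14 Hz); zero-phase filtering is required so the
phase assignment is undistorted.  Epochs are non-overlapping 500-ms
windows with theta/delta RMS ratio > 2.  Cycle boundaries are
positive-to-negative zero crossings of the 5–14 Hz signal within epochs
(phase 0/360, linear interpolation between boundaries).  With this
convention the trough of a cosine-referenced oscillation falls at 90°,
which the synthetic LFP loop verifies to < 15° RMS.  Phase locking is the
mean resultant of per-spike phases with the Rayleigh test Z = nR² and the
standard small-sample p approximation.

Theta-cycle skipping: spike-time autocorrelation (2-ms bins, 0–300 ms);
p1 = maximum count at 100–150 ms, p2 at 200–300 ms; index =
(p2 − p1)/max(p1, p2); skipping above 0.1.  Cluster quality: refractory
ratio = mean counts at 0–1.5 ms over the maximum 5–25 ms count (0.5-ms
bins), discarding above 0.125; isolation distance is the classical
Mahalanobis distance of the n-th closest non-member spike (n = cluster
size) under the cluster's own covariance.

## Landmark-driven changes and their significance

Per-condition tuning curves concatenate all vp1 (resp. vp2) trials.  The
change statistics are the absolute circular change in preferred direction,
the absolute change in HD score, and the relative rate change
|r1 − r2|/(r1 + r2) with r_c = in-condition spikes / in-condition time.
Significance uses a cell-specific trial-label shuffle: labels are
reassigned across the 40 trials (preserving the 20/20 balance — our
choice, matching the design's balance; a free-reassignment variant exists
behind a flag), the statistics recomputed, 500 times; a change is
significant when it strictly exceeds the ⌈0.99 n⌉-th order statistic of
its own null.  Precomputed per-trial histograms make each surrogate a
36-bin re-summation, so 500 shuffles cost milliseconds.  Under the null
the strict rule flags ~6/501 ≈ 1.2% of cells per statistic, which the
calibration experiment confirms.

## Pairwise analysis

Reorganization between conditions for a pair (i, j):
|(PrefHD_j,vp1 − PrefHD_i,vp1) − (PrefHD_j,vp2 − PrefHD_i,vp2)| computed
circularly, and the analogous absolute differences for HD scores and IFR
associations.  The within-condition control applies the same formula to
odd vs even vp1 trials (balanced 10/10 split against slow drift).  Scores
are symmetric in pair order.  Because the within split uses half the data,
within scores are noisier; dissociation tests are therefore one-sided
(between > within).

Theta synchrony: the spike-time crosscorrelogram (±300 ms, 2-ms bins,
counts of j-spikes around each i-spike) is z-scored across its 301 bins
and transformed with a complex Morlet wavelet (ω0 = 6; 30 log-spaced
frequencies over 2–20 Hz; lag axis as time).  Power at each scale is
normalised by the wavelet's squared L2 norm measured from its impulse
response — exactly the expected power of a unit-variance white vector, so
the normalisation is scale-free.  The score is the mean normalised power
at 6–10 Hz within |lag| ≤ 25 ms minus the white baseline of 1, clipped at
zero.  Untuned pairs score ~0–1; theta-locked pairs score orders of
magnitude higher.  Because this scale is not comparable to any particular
colormap normalisation, the pipeline re-derives the LTS/HTS boundary from
the cohort's score distribution (two-component mixture crossing) whenever
at least 10 pairs are available, falling back to the configured default.

Fisher-Z comparison of two independent correlations:
Z = (atanh r1 − atanh r2)/sqrt(1/(n1−3) + 1/(n2−3)), two-sided normal p.

## Synthetic sessions

The generator emulates the statistical structure the estimators assume:

- Trajectory: 2-D Ornstein–Uhlenbeck velocity (per-component sd 9 cm/s,
  τ = 1 s) integrated and reflected at the platform walls, giving a median
  speed near 10 cm/s and speeds spanning 0–40 cm/s.  HD is the motion
  heading (smoothed on the unwrapped circle) plus OU jitter (sd 15°,
  τ = 1 s) — HD sampling is therefore biased by the path, as in real data,
  while still covering all 36 bins within a session.
- LFP: 8-Hz oscillation with slow OU jitter of frequency (sd 0.4 Hz) and
  amplitude, plus 1/f noise at a configurable RMS SNR (default 3).  The
  ground-truth phase is returned alongside.
- Spike trains: inhomogeneous Poisson by thinning at the rate bound, with
  rate λ(t) = gain_c · [b + (peak_c − b) · vonMises(hd; pref_c, κ)] ·
  [1 + depth · cos(φ − φ0)] · place-factor, a 2-ms absolute refractory
  period by thinning, and condition parameters switching instantaneously
  at trial boundaries (the protocol has no dark period between trials).
  Grid cells use the three-cosine hexagonal rate function scaled to
  [0, peak].  A rate bound of 500 Hz guards against parameter mistakes.
- Default cohort (80 min, 40 trials): 6 theta-rhythmic HD cells (κ = 2,
  peak 20 Hz, baseline 0.5 Hz, depth 0.8) rotating coherently by 30° in
  vp2; 6 non-rhythmic HD cells (depth 0) with independent rotations of
  45–135° (random sign) and vp2 rate gains of 0.4–1; 4 grid cells
  (spacing 28–40 cm); 4 untuned Poisson cells (2–8 Hz).  Each object draws
  from its own stream spawned from the master seed.

What the generator does **not** emulate: bursting and other non-Poisson
interval structure beyond the absolute refractory period, phase
precession, slow nonstationarities (electrode drift, fatigue), conjunctive
tuning combinations beyond HD × place, correlated noise between cells
beyond shared behavioral/theta drives, and theta frequency modulation by
running speed.  Passing tests therefore demonstrate correctness of the
estimators and calibration of the tests under the assumed model — not
robustness to every property of real recordings.

## Problem sizes and experiment design

The bundled experiments use: 200 no-effect cells (plus 30 rotated cells)
with 500 shuffles for the calibration of the trial-label test; 34 + 59
cells of 10 min each for the mixture classification; ten 40-trial sessions
with 7 + 7 HD cells and 4 grid cells for the reorganization dissociation
(pairs pooled across sessions, one-sided paired Wilcoxon); and one default
20-cell 80-min session for end-to-end recovery.  These sizes give each
check comfortable statistical resolution (e.g. the calibration's expected
false-positive rate of 1.2% is estimated to ±0.6%) while keeping a full
run in the minutes range on one CPU.

## Known limitations

- The annulus rule and Welch parameters are fixed documented choices;
  other reasonable choices shift grid scores and theta indices slightly
  (the mixture boundary, not the index scale, is the decision variable).
- The theta-synchrony score's absolute scale depends on the wavelet
  normalisation; only the derived LTS/HTS boundary, orderings and the
  bimodality of the distribution are meaningful.
- Curves with undefined bins propagate NaN conservatively; sessions with
  extremely uneven coverage can lose HD bins from DR and change
  statistics (N is adjusted and reported).
- The IFR association uses the behavioral preset on the full session span;
  restricting to condition subsets uses window centers, so windows
  straddling trial boundaries are assigned, not split.
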