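# parahd

Analysis of head-direction (HD) cells recorded in the parahippocampal
region (medial entorhinal cortex / parasubiculum) of mice foraging on a
70 × 70 cm platform while two visual wall patterns (vp1, vp2) alternate in
forty 2-minute trials.

The package answers three questions about such recordings:

1. **Which cells are HD cells, grid cells, speed cells or spatially
   selective cells?**  HD tuning curves (36 × 10° bins, occupancy
   normalised, Gaussian smoothed), firing rate maps (2-cm bins), the HD
   score (mean vector length *R* of the tuning curve), the distributive
   ratio `DR = Σ|ln((1+R_obs)/(1+R_pred))|/N` guarding against
   sampling-bias artifacts, the grid score
   `(r60+r120)/2 − (r30+r90+r150)/3` on the rate-map autocorrelation,
   sparsity and speed scores, each with a cell-specific shuffle threshold
   from circular time shifts of the tracking data.
2. **Is a cell theta-rhythmic?**  The theta index
   `(θ − baseline)/(θ + baseline)` compares the 6–10 Hz power of the
   spike-train instantaneous firing rate against flanking bands
   (3–5 ∪ 11–13 Hz); the population of indices is split into non-rhythmic
   and theta-rhythmic classes by a Gaussian mixture fit with the component
   count chosen by BIC.  LFP theta epochs, cycle-by-cycle spike phases,
   Rayleigh tests and theta-cycle skipping complete the picture.
3. **Do visual landmarks reorganize the HD representation?**  Per cell,
   changes in preferred direction, HD score and mean rate between vp1 and
   vp2 are tested against 500 trial-label shuffles.  Per simultaneously
   recorded pair, the between-condition reorganization score
   `|(PrefHD_j,vp1 − PrefHD_i,vp1) − (PrefHD_j,vp2 − PrefHD_i,vp2)|`
   (and its HD-score and IFR-association analogues) is compared with the
   within-condition control computed on two disjoint halves of the vp1
   trials.  Theta synchrony of a pair is the Morlet wavelet power of the
   z-scored spike-time crosscorrelogram at 6–10 Hz near zero lag.

A fully seedable synthetic-session generator (von Mises HD tuning,
theta-modulated inhomogeneous Poisson spiking, hexagonal grid fields,
condition-dependent rotations and gain changes, jittered-theta LFP with
1/f noise) provides ground truth for every stage, so the whole pipeline is
testable without any recorded data.

## Worked example

```python
from parahd import build_synthetic_session, run_pipeline, PipelineConfig

session, truth = build_synthetic_session(seed=42)   # 20 cells, 80 min
bundle = run_pipeline(session, PipelineConfig(), seed=1)
print(bundle.summary["labels"])
print(bundle.summary["theta_index_threshold"])
print(bundle.pairs.groupby("pair_class")[["between_pref", "within_pref"]].median())
```

prints

```
{'HD': 12, 'grid': 4, 'other': 4}
0.10729661548041847
                between_pref  within_pref
pair_class
mixed              69.164547     0.785473
non-rhythmic      109.874764     0.951467
theta-rhythmic      1.045128     0.861406
```

All 12 simulated HD cells (6 theta-rhythmic with a coherent 30° rotation
in vp2, 6 non-rhythmic with independent rotations), 4 grid cells and 4
untuned cells are recovered; the mixture boundary between non-rhythmic and
theta-rhythmic theta indices lands near 0.11; and the pairwise table shows
the central dissociation — non-rhythmic pairs reorganize their preferred-HD
differences between conditions (median 110° against a 1° within-condition
control) while theta-rhythmic pairs do not (1.0° vs 0.9°).

The same pipeline is available from the shell:

```bash
parahd simulate --seed 42 --out session/
parahd analyze --session session/ --seed 1 --out results/
parahd report --results results/
```

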