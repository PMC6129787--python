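# mstate

EEG microstate analysis of executed and imagined hand-grip force.

Multichannel EEG can be described as a sequence of brief (~80–120 ms up to
seconds, in task designs) periods during which the scalp potential
topography stays quasi-stable before switching to another configuration —
*microstates*.  This package implements the complete microstate pipeline
for a 2×3 hand-grip study design ({executed, imagined} × {4, 10, 16 kg}
force targets) over 9 sensorimotor channels (FC3, FCz, FC4, C3, Cz, C4,
CP3, Pz, CP4):

1. **Preprocessing** (`mstate.io_preprocess`) — EDF or delimited-matrix
   input, downsampling to 125 Hz, zero-phase FIR band-pass 0.05–45 Hz,
   epoching, baseline correction, common-average re-referencing, and
   averaging of same-condition trials.
2. **Global field power** (`mstate.gfp`) — the spatial standard deviation
   of the scalp map,
   GFP(t) = √(Σᵢ (Vᵢ(t) − V̄(t))² / k),
   and its local maxima (samples exceeding the 4 preceding and 4 following
   samples), whose topographies carry the highest signal-to-noise ratio.
3. **Clustering** (`mstate.cluster`) — a modified k-means over peak
   topographies using polarity-invariant spatial Pearson correlation, with
   the number of classes selected by (a) 100× repeated, stratified 80/20
   cross-validation scored as the mean maximal test-map correlation, with
   a parsimony tie-break, and (b) pseudo-F (Calinski–Harabasz) and
   pseudo-t² (Duda–Hart) scatter statistics,
   F = ((T − P_k)/(k − 1)) / (P_k/(n − k)),
   t² = B²_pq / ((W_p + W_q)/(n_p + n_q − 2)).
4. **Backfitting** (`mstate.segment`) — per-sample class labels by region
   filling between peaks (or per-sample matching), maximal runs, and the
   microstate *syntax* (run sequence and transition matrix).
5. **Parameters** (`mstate.params`) — per class: duration Dur = MST/CON,
   occurrence, time coverage TC = MST/WT, and amplitude (mean peak GFP)
   over a 3.5 s analysis window.
6. **Band correlation** (`mstate.bandcorr`) — Pearson correlation between
   each microstate's GFP and channel-averaged band power (delta, theta,
   mu, beta, gamma).
7. **Statistics** (`mstate.stats_report`) — 2×3 two-factor ANOVA (main
   effects, type-II) and the nine pairwise condition comparisons, with
   Holm-adjusted p-values alongside.

Because grip-force EEG with ground truth is not publicly available, the
package ships a first-class synthetic-data generator (`mstate.synth`) that
plants a known template set, switching schedule (A during the 0–0.5 s
preparation period, then B, then C, with the B→C switch moving earlier as
force rises), mu/beta carrier content and sensor noise — so every stage of
the pipeline is validated against exact ground truth.

## Worked example

```sh
mstate run --seed 1 --out out/
```

runs the full pipeline on a simulated study (4 subjects × 6 conditions ×
2 trials, SNR 2) and prints

```
selected k = 3 (cv=3, F=3, t2=3); GEV = 93.2%
tables and manifest -> out/
```

All three class-count criteria agree on 3 microstate classes — the
cross-validation curve rises to 0.936 at k = 3 and gains < 1% beyond it,
pseudo-F peaks at k = 3 (1876), and pseudo-t² collapses from 1188 (k = 3)
to 47 (k = 4) — and the fitted 3-class model explains 93.2% of the
topographic variance of the peak maps.  `out/params_summary.csv` shows the
planted physiology recovered from the data (means over subjects):

| condition      | class | duration (ms) | coverage (%) | amplitude (µV) |
|----------------|-------|--------------:|-------------:|---------------:|
| executed_4kg   | B     | 1469          | 60.1         | 3.36           |
| executed_10kg  | B     | 1351          | 43.6         | 4.50           |
| executed_16kg  | B     | 1088          | 35.3         | 5.51           |
| executed_4kg   | C     | 716           | 26.8         | 3.43           |
| executed_10kg  | C     | 1288          | 42.4         | 4.72           |
| executed_16kg  | C     | 1546          | 50.7         | 5.71           |

i.e. microstate B's duration and coverage shrink with rising force while
C's grow, amplitudes rise with force and are larger for executed than for
imagined conditions, and the modal syntax across recordings is A→B→C
(`out/syntax.csv`).  `out/anova.csv` and `out/pairwise.csv` hold the
two-factor ANOVA and the nine comparison groups per parameter and class.

The same stages are available piecemeal (`mstate simulate|preprocess|
peaks|cluster|segment|params|bandcorr|stats`) and as plain library calls;
every randomized step takes an explicit seed and the run manifest records
the configuration and decisions taken.

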