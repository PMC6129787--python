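# Methods

## The model

The pipeline treats multichannel EEG as a succession of quasi-stable scalp
topographies.  At each sample the global field power (GFP) — the spatial
standard deviation over the k electrodes — measures how strongly a
topography is expressed; its local maxima (strictly greater than the 4
samples on each side) are the instants of highest topographic
signal-to-noise ratio.  The peak topographies, taken mean-free and (for
clustering) normalized to unit GFP, are grouped into a small number of
classes by topographic shape; the whole time series is then *backfitted*
(every sample labeled with a class), and per-class summary parameters and
class-to-class transition structure are computed per experimental
condition.

Polarity is ignored by default (similarity is |spatial Pearson r|): EEG
oscillations flip the sign of a topography at the rhythm rate without
changing the underlying configuration.  A signed mode is available.

## Synthetic data

Real grip-force EEG with per-sample ground truth does not exist, so the
generator plants it:

    data(t) = a · c(t) · m_{z(t)} + ε(t)

* `m_1..m_K` — zero-mean, unit-GFP random topographies with pairwise
  |spatial r| ≤ 0.5 (rejection sampling; 9 channels, 3 classes by
  default).
* `z(t)` — the planted schedule: class A occupies the 0–500 ms task
  preparation period; B and C split the remaining 3 s of the 3.5 s window,
  with the B→C switch moving earlier as the force target rises
  (B durations 2008/1543/1254 ms executed, 2220/1762/1562 ms imagined for
  4/10/16 kg).  Segments are half-open in ms; sample n belongs to the
  segment containing n/rate; 3.5 s at 125 Hz gives 438 samples.
* `c(t)` — a signed sum of band-limited sinusoid mixtures (8 random
  components per band; mu 8–14 Hz at weight 1.0 plus beta 14–20 Hz at
  0.5), normalized so mean |c| = 1.  Multiplying the template by the
  *signed* carrier (rather than by its rectified envelope) keeps the
  signal's spectral energy genuinely in the mu/beta bands — required for
  the band-power analysis to mean anything — while GFP follows |c(t)| and
  therefore peaks throughout every segment.  The polarity flips at the
  carrier rate are exactly the reason the analysis is polarity-invariant.
* `a` — per-condition amplitude scale: 2.16/2.82/3.54 µV (executed) and
  1.82/2.18/3.37 µV (imagined) for 4/10/16 kg, so `a` is the mean
  noiseless GFP of the condition.  An optional log-normal gain jitter
  (SD 0.1 of the log in the pipeline default) emulates between-recording
  variability.
* `ε(t)` — white Gaussian noise, scaled so the RMS-amplitude ratio of
  clean signal to noise equals the configured SNR (default 2).

The carrier seed is shared across conditions within a trial index, so
noiseless between-condition GFP ratios equal the configured scale ratios
exactly; noise is independent per condition × trial.

What the generator does **not** emulate: volume conduction and realistic
channel covariance (noise is white across channels by default), 1/f
background spectra, artifacts (EOG/EMG), gradual topography morphing, or
within-class topographic variability.  Passing tests therefore demonstrate
the pipeline's correctness and its behavior under controlled mixing of
topographies, rhythm and noise — not performance on human EEG.

## Preprocessing

Canonical order: import → downsample (anti-alias FIR at 0.4 × target,
then decimation; polyphase resampling for rational ratios) → zero-phase
windowed-sinc band-pass (Hamming, 0.5 Hz transition at the low edge,
forward–backward application) → epoching (default −1.5 to +3.5 s around
task onset) → per-channel baseline subtraction (−1.5 to +0.5 s) →
artifact hook (a pass-through honoring an external bad-trial mask; ICA is
out of scope) → common-average re-referencing (which provably leaves GFP
unchanged) → averaging of same-condition trials.  A true 0.05 Hz FIR edge
would need tens of thousands of taps, so for `low > 0` each channel is
demeaned exactly first and the FIR handles in-band shaping.  The two
window conventions in circulation (0.5–3 s extraction vs. the 3.5 s
analysis window including the preparation period) are both configurable;
the default analyzes the full 3.5 s window.

## Class-count selection

* **Cross-validation**: 100 random stratified 80/20 splits (every
  condition stratum contributes to both sets).  For each candidate k,
  templates fitted on the training peaks score the held-out peaks by the
  mean maximal |spatial r|; curves are averaged over repetitions.  The
  score is non-decreasing in k by construction, so selection uses a
  parsimony rule: the smallest k within 1% (relative) of the best mean
  correlation.  A flat curve (range < 10⁻³) expresses no preference and
  defers to the pseudo statistics.
* **Pseudo-F** (Calinski–Harabasz): computed per k from an independent
  k-means fit, on unit-GFP maps sign-aligned to their assigned template
  (so amplitude never drives the statistic, and the within/total scatter
  decomposition P_k ≤ T holds exactly).  The indicated k is the first
  interior local maximum of the curve, else its argmax.
* **Pseudo-t²** (Duda–Hart): for each k, the merge that would take the
  k-solution to k−1 classes (the pair minimizing the pooled within-class
  scatter increase, Ward-style) is scored by
  t² = B²/((W_p+W_q)/(n_p+n_q−2)) with B² = W_merged − W_p − W_q.  Because
  B² of a pair-union merge is nonnegative, the classical
  positive-to-negative transition appears as a collapse from
  cluster-scale to noise-scale values; the indicated k is the literal
  sign-change point when one exists, otherwise the change point of the
  collapse (maximal ratio t²(k)/t²(k+1)).  A plain argmax was rejected: on
  planted-3 data t²(2) ≈ t²(3) ≫ t²(4), so the argmax expresses no
  transition.
* The selection combines the three: the CV winner is authoritative, the
  pseudo statistics cross-check it, and disagreements are recorded in the
  result rather than resolved.

Known limitation: with the class imbalance this task design implies
(class A covers only ~14% of the window), pseudo-F retains the
Calinski–Harabasz bias toward k = 2 in a minority of noise realizations —
verified to persist under the true labeling, more restarts, nested
agglomeration and full trial averaging — while the cross-validation rule
and the t² transition are markedly more reliable on the same data.

## Backfitting and parameters

Default backfitting assigns each peak to its best template and fills the
region between peaks by temporal proximity (ties to the earlier peak;
edges extend the first/last peak's label), so every sample is labeled and
coverages sum to 100%.  The alternative per-sample mode labels each sample
independently; it has no boundary quantization but is noisy at GFP
troughs, where the map carries little information — run smoothing (minimum
run duration, shorter runs absorbed into the neighbor with the higher
boundary template correlation; 0 = off by default) cleans those flips.
Boundary identifiability is inherently limited by the carrier trough
width: on 4-trial condition averages at SNR 2 the per-class labeled time
is recovered with a mean error < 2 samples per planted boundary, while
single realizations whose boundary falls inside a trough can err by the
trough width.

Per class within the window WT (3.5 s default; the effective value
n_samples/rate is used as the TC denominator so coverages sum to exactly
100%): MST (total labeled time), CON (number of maximal runs),
Dur = MST/CON, TC = MST/WT, occurrence (number of GFP peaks of the class;
reported both as a count in WT and per second, since both conventions
appear in practice), GFPP (summed peak GFP) and amplitude.  The amplitude
denominator defaults to the peak count (mean peak GFP, µV scale); the
literal GFPP/CON variant is selectable.  Dur·CON = MST is asserted on
every emitted record.

Class letters A, B, C… are assigned by order of first temporal occurrence
after backfitting, scanned over all recordings of a run, making labels
comparable across runs up to that rule.

## Band correlation

Band power is the squared band-passed signal (same FIR design), averaged
over channels and smoothed with a 250 ms moving average; the temporal
resolution of a "mean band power" series is a free choice and is
configurable.  For each class, the GFP values at that class's samples are
paired with the band power at the same samples and summarized by
Pearson's r.  Default bands: delta 1–4, theta 4–8, mu 8–14, beta 14–20,
gamma 20–40 Hz.  A legacy tabulation that lists theta as 14–20 Hz
(duplicating beta) is selectable for literal replication but is treated
as a typo by default.

## Statistics

Microstate parameters are analyzed with subject-level observations: a 2×3
two-factor ANOVA (mode × force, main effects only, type-II sums of
squares via statsmodels OLS) and nine pairwise condition comparisons
(one-way F tests: the three force pairs within each mode, and the three
matched-force mode contrasts).  p-values are reported uncorrected at the
0.05 convention, with a Holm-adjusted column emitted alongside as modern
hygiene.

## Numerical choices

* K-means: random-row initialization, best of n restarts by total
  explained similarity (Σ r² in invariant mode), iteration cap 500,
  convergence on unchanged assignments; empty clusters are re-seeded from
  the worst-fitted map.  Template update: first principal direction of
  the assigned maps (invariant) or their normalized mean (signed).
  Restart defaults: 3 inside cross-validation (fit quality vs. ~7,000
  fits per study), 10 for final and pseudo-curve fits.
* Ties and degenerate inputs: strict inequality in peak detection (a
  plateau yields no peak); zero-variance maps are rejected in similarity
  computations and correlate 0 in per-sample backfitting; pseudo-F is 0
  when T = 0 and +∞ when P_k = 0 < T; pseudo-t² is 0 when B² = 0 and +∞
  on a zero denominator with B² > 0.
* EDF output uses the package's own 16-bit writer (single data record,
  physical range per channel from the data), accurate to the quantization
  step; reading goes through MNE.
* Problem sizes: the bundled study configuration uses 6 conditions ×
  4 trials with two 2-trial session averages per condition (~45 GFP peaks
  per averaged recording, ~550 pooled peaks per study), and the recovery
  analyses use 20 independent studies; these sizes give stable selection
  statistics while keeping a full analysis in seconds.
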