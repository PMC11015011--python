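# Methods

`offsemble` re-implements, as a tested pipeline over synthetic data, an
unsupervised analysis of visual-cortex population activity: binary rasters
are derived from calcium fluorescence, repeated population patterns
("ensembles") are detected without any stimulus information, each ensemble is
decomposed into coactivated members (the onsemble), specifically inactivated
members (the offsemble), and nonparticipants, and the resulting units are
compared on orientation selectivity, tuning width, and stimulus decoding.
This note documents the model, the defaults, and the judgment calls.

## Synthetic sessions

The generator emulates a head-fixed mouse viewing full-field drifting
gratings during volumetric two-photon imaging (three planes, one effective
frame clock at 81 ms).

**Schedule.** Gratings drift in 8 directions (4 orientations), 2 s per
trial, inter-stimulus blanks uniform on 1–5 s, at least 6 repetitions of
each direction in a 5-minute session (at least 48 trials).  Directions are
drawn in shuffled balanced blocks, so repetition counts differ by at most
one; trials are packed until the session ends, which typically yields
~60 trials.

**Population.** Defaults follow the population scale the pipeline is
designed for: 538 neurons per session in the realistic regime (200 in the
quick default config), four ensembles, one per orientation.  Per ensemble,
20% of neurons are onsemble members and 26% offsemble members.  54% of each
onsemble is shared with other onsembles, with shared members drawn
preferentially from ensembles of similar orientation (sharing weights follow
the tuning-width Gaussian of the orientation difference).  Offsembles draw
47% of their members from other ensembles' onsembles (cross-orientation
suppression), 38% from an interstimulus-preferring pool (18% of the
population), and the rest from otherwise untuned neurons.  Derived
single-cell classes: a neuron in exactly one onsemble is "tuned" to that
orientation, in several onsembles "unspecific", in the interstimulus pool
"interstim", otherwise "untuned".

**Spiking.** Per-frame Bernoulli events.  The default rates are the
onset-aligned active fractions typical of such recordings, read as per-frame
event probabilities: baseline
0.2/frame (20% of neurons active per frame before an ensemble onset), evoked
gain 2.9 (58% of onsemble members active at the evoked peak), suppression
factor 0.4 (offsemble fraction dropping to 8%), interstimulus gain 2.
Evoked drive is scaled by a Gaussian of the orientation difference with a
35° width, the reported single-neuron tuning-width scale; this spillover is
what makes shared and unspecific membership behaviorally real.

**Calcium.** Each event adds an instantaneous-rise transient (amplitude
0.2 ΔF/F, the single-event scale of the slow indicator emulated) that decays
exponentially with τ = 5.8 s; while a neuron's suppressing stimulus is on,
the decay constant switches to 2.5 s — the signature of selective
inhibition this analysis is built to detect — implemented as a time-varying AR(1) coefficient.  ROI
fluorescence is calcium + shared slow background + Gaussian noise
(σ = 0.02); neuropil fluorescence is the background + independent noise.
These scales put the PSNR of quiet neurons near the 10–20 dB range the QC
rule was written for.

**Behavior.** Running comes in 2–8 s bouts with still bouts sized to a
target running fraction (speed > 1 cm/s during bouts); whisking energy is
elevated during wakeful epochs.  All randomness flows from one root seed
through named substreams (schedule / membership / spikes / noise /
behavior), so each stage is independently reproducible.

## Preprocessing

Neuropil-normalized signal (F_ROI − F_neuropil)/F_neuropil; per-ROI peak
signal-to-noise ratio 20·log10(max(F_ROI − F_neuropil)/std(F_neuropil));
ROIs strictly above 10 dB are kept ("above" read as strict >, configurable).
Kept traces pass through sequential moving median, minimum, and maximum
filters with a 0.5 s window (rounded to an odd frame count, truncated at the
edges), then AR(1) sparse nonnegative deconvolution (an online
pool-adjacent-violators solver for min ½‖c−y‖² + λΣs, s_t = c_t − γc_{t−1}
≥ 0), then binarization at the PSNR-proportional threshold
max(0.04 − 0.002·PSNR, 0.01).

Numerical choices worth knowing:

- **γ defaults to exp(−Δt/5.8 s).**  An AR(1) coefficient smaller than the
  data's true decay turns every decay frame into a spurious positive spike,
  so the indicator time constant defaults to the spontaneous GCaMP6s-scale
  decay rather than a faster nominal value.  Mismatch in the other direction
  (suppressed, faster decays) only clips to zero and is harmless.
- **λ** defaults to the MAD of the high-pass residual (trace − smoothed).
- **Threshold floor 0.01 and a plateau guard.**  The min→max pair of the
  smoothing is a morphological opening that flattens each transient peak
  into a plateau one window long; exact AR(1) deconvolution of a plateau
  leaks increments of (1−γ) × fluorescence (~1.4% per frame).  Binarization
  floors the threshold at 0.01 (instead of ~0) and suppresses deconvolved
  increments below 2(1−γ) × the local smoothed fluorescence, which is
  exactly the artifact scale.  With these guards, the full chain recovers
  sparse spike trains nearly perfectly (Jaccard ≥ 0.9 round trip on
  noiseless data); trains denser than the 0.5 s window cannot be resolved
  event-for-event by construction, and recovered rates compress accordingly.

**Decay fitting.**  Single-exponential a·e^{−t/τ} by bounded nonlinear least
squares (τ ∈ [0.05, 20] s; log-linear start; fits landing on a bound are
flagged, not returned silently).  Transient detection for the
decay-by-condition analysis is a documented stand-in: local maxima above
3×MAD followed by ≥ 0.5 s of non-increasing signal (5% tolerance), window to
the next rise or 2 s.  Windows fully inside a trial of the neuron's
suppressing orientation are "during"; windows whose peak precedes such an
onset are clipped at the onset and counted "pre-onset"; windows touching no
stimulus are "spontaneous".  Because suppression accelerates an *ongoing*
decay rather than creating a peak, trial onsets where the signal is already
elevated and falling are also taken as "during" windows.

## Ensemble detection

1. **Functional network.**  Edge (i, j) iff the observed coactivation count
   strictly exceeds the empirical 95th percentile of a circular-shift
   surrogate null (1000 surrogates).  Shifting two trains independently
   changes coactivation only through the relative offset, so the null is
   read off the FFT circular cross-correlation at random nonzero offsets —
   distributionally identical and far cheaper.  No multiple-comparison
   correction by default (a Bonferroni flag exists but empirically
   fragments the network and hurts pattern recovery).  Because coactivation
   counts are small integers, the strict > against an empirical quantile is
   conservative under ties; the null edge rate sits near, slightly below,
   the nominal level.
2. **Raster filter.**  In each frame a spike is kept iff its neuron has at
   least one network neighbor active in the same frame; unstructured frames
   empty out.
3. **Clustering.**  All-zero frames are excluded; the remaining population
   vectors are clustered hierarchically with Ward linkage on 1 − Jaccard
   (Ward applied to the precomputed non-Euclidean distance, the common
   dialect).  The tree is cut at every k in [2, 10].
4. **Contrast index.**  Per cluster, mean within-cluster similarity minus
   mean similarity of members to non-members, averaged over clusters
   (singletons contribute within-similarity 1).  k* maximizes the index;
   ties go to the smallest k.
5. **Significance.**  For a cluster of m frames, the observed mean pairwise
   similarity is compared to 1000 draws of m random clustered frames
   (z-test, one-sided p; a zero-variance null falls back to the exceedance
   fraction).  Clusters with p < 0.05 are ensembles; their occurrence
   signals are binary and mutually exclusive by construction.

## Participation

**EPI.**  EPI = (r_in − r_out)/(r_in + r_out), the normalized difference of
a neuron's event rate during the ensemble's occurrences and outside them.
+1 means exclusively active during occurrences, −1 exclusively outside
(inactivated), 0 equal rates.  This normalization was chosen over the
spike-count ratio 2·(inside/total) − 1 because the count form flips sign
for genuinely activated neurons whenever occurrences are much shorter than
the session (and for neurons shared between ensembles); the two coincide
when occurrence and non-occurrence windows are equally long, which is how
the anchor values ±1 and 0 are defined.

**Significance.**  Welch two-sample t-test on per-epoch activity fractions:
one sample per occurrence run, one per inactivity epoch, where the
inactivity gaps are split into chunks of the median occurrence length
("matched" epochs, equalizing per-epoch variance).  Other ensembles'
occurrences — dilated by 3 frames, half the smoothing window, since events
cannot be localized more finely — are excluded from the inactivity epochs,
so a neuron driven by a different ensemble is not mistaken for a suppressed
one.  If that exclusion would blanket the complement (a tonic ensemble
tracking the interstimulus periods can cover it entirely), the
largest-occupancy signals are released from the exclusion until at least a
quarter of the complement remains.  Classification: onsemble iff p < 0.05,
EPI > 0 and the epoch contrast is positive; offsemble iff p < 0.05, EPI < 0
and the contrast negative; otherwise nonparticipant.  No correction across
neurons (per-neuron p < 0.05, mirroring common practice in this literature; a BH option would
be a one-line change in the caller).

Known property: event-based cluster assignment anti-selects frames with
non-member activity, so a small fraction of genuinely uninvolved neurons
shows a weak but significant rate dip during claimed occurrences.  This
false-participation floor is intrinsic to the method, grows with baseline
rate, and is why membership-recovery benchmarks use the sparse clean regime
(below).

## Tuning and decoding

Trial responses are mean activity over each 2 s stimulus window, in [0, 1]
(binary for neurons and ensemble signals; fraction-of-members for groups;
directions θ and θ+180° pool to four orientations).  Selectivity is
1 − CirVar with doubled angles; significance is a one-sample Hotelling t²
on the vectors R_t(cos 2θ_t, sin 2θ_t) against zero (F reference; a
singular covariance falls back to a deterministic permutation test).  Under
a balanced fixed design this test is conservative for untuned units — the
between-orientation spread inflates the trial covariance — which is the
intended behavior of the procedure, not a defect.  Tuning width comes
from a bounded Gaussian fit a·exp(−Δθ²/2σ²) with wrapped angular distance,
a ∈ [0, 1], θ_pref ∈ [−45°, 180°], σ ∈ [1°, 90°]; fits at a bound are
flagged.  Single cells that fail the Hotelling test are split by a Welch
t-test of per-period activity, stimulation vs interstimulus: higher during
stimulation → "unspecific", higher between → "interstim", neither →
"untuned".

Decoding scans every distinct response value as a cutoff in both inequality
directions and keeps the operating point maximizing informedness (hit rate
minus false-alarm rate); the ≤ direction lets anti-responsive (offsemble)
units act as predictors without special-casing.  Four predictors, one per
orientation, vote by largest signed margin past their operating point
(covering the none-fire and multi-fire cases); exact ties break by a seeded
uniform choice.  Accuracy is the confusion-matrix trace over total trials.
Neuron-level decoding assembles disjoint random quadruples (one tuned
neuron per orientation) until the smallest orientation pool is exhausted
and averages the count matrices.

**Group activation criterion.**  For fraction-of-members series (groups),
"active" for the activation-probability and duration analyses means above
the session median of the series (binary units use > 0); no standard criterion exists for fractional series, and the median is the
neutral choice.

**Removal control.**  The union of offsemble members of orientation-tuned
ensembles is removed, or — as the matched control — an equal count of
neurons that participate in no such ensemble, taking those with the
smallest mean |EPI| ("least participating").  Detection re-runs with k
forced to the original significant-pattern count, and the outputs compared
are the number of orientation-tuned patterns and their mean selectivity and
width, paired across seeds.

## Benchmark regimes

- **Clean regime** (recovery benchmarks): 200 neurons, disjoint onsembles,
  10° tuning width (no cross-orientation spillover), no interstimulus pool,
  sparse high-contrast rates (baseline 0.02/frame, gain 25, suppression
  0.1), analysed on the true spike raster.  Here planted frame labels and
  memberships are unambiguous, so adjusted Rand index and per-class F1 are
  meaningful; detection recovers the four patterns at ARI ≈ 1 and
  membership F1 ≥ 0.9 per class.
- **Realistic regime** (ordering and decoding benchmarks): 538 neurons,
  full sharing/composition defaults, dense calibrated rates, full
  fluorescence chain.  Here the planted labels are deliberately ambiguous
  (spillover, sharing, selection effects), and the benchmarks are the
  qualitative orderings: ensembles are the most selective and narrowest
  units, then tuned single neurons, then the onsemble/offsemble member
  fractions, then the nonparticipant-tuned population, with tuning widths
  ordered inversely; ensemble decoding is near-perfect and beats averaged
  neuron quadruples.
- The removal-control cohort uses 120-neuron, 4-minute sessions through the
  full chain with 500 surrogates/iterations, sized so a 20-session paired
  cohort runs in a few minutes.

## What the generator does not emulate

No pixel-level imaging, motion artifacts, or ROI segmentation errors; no
plane-by-plane timing beyond one effective frame period; neuropil
contamination is a shared global background rather than spatially local;
spike trains are Poisson-like (Bernoulli per frame) without refractoriness,
bursting, or adaptation; trial-to-trial variability is purely binomial.
Passing tests therefore show that the analysis recovers the structures it
assumes, at realistic scales and noise — not that those structures exhaust
real cortical data.

A further documented divergence: with the rate-contrast EPI and mutually
exclusive occurrences, the ensemble-fraction ("ensemble†") series — active
onsemble members plus silent offsemble members — carries little orientation
information when baseline rates are low, because offsemble members are
almost always silent everywhere; its selectivity is only meaningful in
dense-rate regimes.
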