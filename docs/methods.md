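# Methods

This note documents the models and procedures implemented in `hippocoact`,
the assumptions behind them, the synthetic study conditions used to verify
them, and the numerical choices made where the procedure leaves room.

## Signals and conventions

Time is in seconds (float64) on one session clock; sample indices are
0-based; all event and counting windows are half-open `[start, end)`.
Channels are ordered along the probe from CA1 stratum oriens down to the DG
granule cell layer, with layer labels drawn from
`{ori, pyr, rad, lm, om, mm, im, gcl, unknown}`. Filtering is zero-phase
(forward–backward) everywhere: this is an offline pipeline, detection
latency is not at issue, and phase distortion would bias event peak times.

Decimation from 20 kHz to 1250 Hz uses the 8th-order Chebyshev type I
anti-aliasing decimator, applied in two ×4 stages (single-stage IIR
decimation beyond factor ~13 is numerically fragile). The Chebyshev
passband ripple means a DC input re-emerges constant but attenuated by
~2 %; this is a property of the filter, not an implementation artifact.

## Event detectors

**Dentate spikes.** 1–200 Hz band-pass (4th-order Butterworth), threshold
`6 × median(|filtered|)`. The median-absolute-value threshold makes
detection invariant to global gain. Within any 50 ms frame only the
largest peak is kept; equal-amplitude ties keep the earlier peak
(deterministic). Onset/offset are reported as the half-threshold crossings
around the peak — the amplitude criterion itself defines no extent.
Session-level mean and s.d. of the filtered trace are retained as
diagnostics only. With several granule-layer channels, each is scanned and
the channel with the largest mean DS amplitude supplies the timestamps.

**Sharp-wave ripples.** Per pyramidal channel, the common average across
all channels is subtracted, the residual band-passed 80–250 Hz, and the
analytic-signal (Hilbert) envelope thresholded at `5 × median(envelope)`;
onset/offset where the envelope decays below half the threshold. Three
acceptance criteria: (i) event ripple power ≥ 2× the ripple power of the
common-average trace over the same window (common-mode noise), (ii) ≥ 4
ripple cycles, counted as positive-going zero crossings of the band-passed
trace between onset and offset (the cycle-counting rule had to be fixed by
choice; zero crossings are insensitive to amplitude asymmetries),
(iii) ripple power ≥ 2× the 200–500 Hz power (spike-leakage artifacts).
Band powers are mean squared band-passed signal over `[onset, offset)`.
Events come from the channel with the largest mean ripple envelope.

**Theta cycles.** An oscillatory theta component is extracted by masked
empirical-mode sifting: cosine masks at a dyadic ladder of frequencies
(fs/4, fs/8, … past the theta band), four mask phases per level, cubic-spline
envelope sifting, and the theta component is the sum of intrinsic mode
functions whose zero-crossing frequency falls in 5–12 Hz. A 5–12 Hz
band-pass fallback sits behind `method="bandpass"`; the cycle-acceptance
rules are identical in both paths. A component carrying < 0.25 % of the
signal power is treated as sift/filter residue (aperiodic input → empty
list). Cycles are peak–trough–peak triplets with both half-cycle intervals
in [31, 100] ms and peak-to-peak distance in [71, 200] ms.

Detected DS and SWR whose peaks fall within ±50 ms of each other are
excluded from all event-nested statistics; the pre-exclusion co-occurrence
rate is reported.

## CSD and DS typing

CSD at interior channel n is `−(LFP[n−1] − 2·LFP[n] + LFP[n+1])` (equal
spacing assumed; linear depth profiles map to exactly zero). **Sign
convention:** with positive-up LFP, sinks are negative CSD values; the
procedure's "strongest sink" is operationalized as the most negative value.
Events are typed on their peak-time CSD depth profiles: PCA to two
components, then a 2-component Gaussian mixture (k-means initialization,
10 restarts, best likelihood, fixed seed). The component whose mean profile
has its most negative CSD at the most superficial molecular-layer channel
(search band = channels labeled om/mm/im; ties break superficial) is DS₁;
the other, with the sink nearer the granule layer, DS₂. If the two mixture
means collapse (separation < 10⁻³ of the projection scale) a warning is
raised and a single-class labeling returned.

The waveform-only classifier uses 400 ms granule-layer epochs around each
DS peak, low-passed at 50 Hz and resampled to 500 bins of 0.8 ms, each
epoch divided by its peak absolute value (the normalization had to be
fixed by choice; max-normalization preserves shape and discards gain).
PCA retains 90 % variance; 20 linear discriminants are trained on
independent random 75/25 splits and the best held-out model kept, with the
full accuracy distribution reported.

## Unit metrics

* **Waveform score** `sqrt(Σ(wᵢ/σᵢ)²/n)` — the RMS of the mean waveform
  relative to its spike-to-spike s.d. Inclusion: score > 0.75 and
  fraction of inter-spike intervals strictly below 2 ms under 2 %.
* **Cell class** — 1-D, 2-component Gaussian mixture on trough-to-peak
  widths; the threshold is the crossing of the two weighted component
  densities, found by grid scan at 10⁻³ ms resolution between the means
  (an analytic solution exists but the scan is robust to equal-variance
  degeneracies). Widths above threshold → principal cell. On unimodal
  input a warning is raised; a fixed 0.425 ms threshold is available
  behind a flag.
* **PETH** — 400 bins of 1 ms spanning ±200 ms around event peaks; rates
  z-scored over the window (so the window mean is the activation
  baseline) and smoothed with a 3-point moving average (reflective edge
  padding). Zero-variance histograms set z ≡ 0 and are flagged. A unit is
  *activated* when smoothed z within ±20 ms of the peak exceeds 3
  (suppressed below −3); calls are also reported over a 2 < z < 4 sweep.
* **Place maps** — 1.4 × 1.4 cm bins; spike-count and occupancy maps are
  each smoothed with a 2-D Gaussian (s.d. 1.2 bin widths) using
  truncated-kernel renormalization at edges and unvisited bins, then
  divided. Unvisited bins stay masked, never infinite. Spatial
  information is `Σ pᵢ (λᵢ/λ) log2(λᵢ/λ)` over visited bins, in bits per
  spike; a zero mean rate warns and returns 0.

## Population vectors

Event vectors count spikes of simultaneously recorded principal cells in
`[peak−25 ms, peak+25 ms)`. Baseline windows are sampled uniformly without
replacement from a 50 ms grid over the admissible complement (no window
center within 250 ms + half-window of any event peak), count-matched to
the events. Session inclusion requires ≥ 100 events per compared type and
≥ 20 cells (overridable with a warning). Pre/post control windows use the
200–250 ms epochs before/after the peak.

Gini sparsity is computed on ascending-sorted counts; all-zero vectors are
excluded and counted. The DS-vs-SWR logistic classifier binarizes counts,
balances classes by subsampling the larger, and uses 75/25 splits; because
one subsample is arbitrary, the analysis repeats over 20 subsample/split
seeds and reports the distribution. The logistic model carries a tiny ridge
(C = 1000) purely to keep separable data finite. Similarity (Pearson and
Jaccard) is computed on binarized vectors for both metrics (a counts-based
Pearson sits behind a flag); event counts are matched by subsampling to the
smallest type. Dimensionality is the number of principal components
reaching 90 % cumulative variance on the events × cells count matrix,
scaled by the cell count, with a sweep over variance targets.

## Coactivity and reactivation

The pair model `x_j ~ β_ij·x_i + α_ij·P` is fit by least squares on
z-scored event-nested counts — the inputs being z-scored makes
link/family choices immaterial to the ordering of β, so the identity-link
Gaussian fit is exact, not an approximation. Constant units are dropped
with a report. The matrix is symmetrized `(A + Aᵀ)/2` with zero diagonal.

The clustering coefficient normalizes by the **maximum signed** weight, as
the formula is written; normalized magnitudes can exceed 1 when negative
weights dominate, and the degenerate case max(β) ≤ 0 raises rather than
guesses. The ordered-pair sum counts (j, q) and (q, j) both, consistent
with the `kᵢ(kᵢ−1)` denominator giving Cᵢ = 1 on the maximal all-positive
triangle. Cube roots are real signed roots, so a triad contributes with
the sign of its edge-weight product. Node strength is the off-diagonal row
mean. No same-tetrode pair exclusion is applied by default.

Reactivation fits `post ~ β₀ + β_theta·theta + β_pre·pre + υ_mouse + e` by
REML with a mouse random intercept, and the reverse model with pre and post
swapped. A single mouse falls back to ordinary least squares with a
warning. Fixed-effect t statistics use residual degrees of freedom
(n_pairs − 3). A singular random-effect covariance (mouse variance on the
zero boundary) is reported on the result, never silently absorbed — the
fixed-effect estimates remain valid there. The shuffle null permutes theta
weights across cell pairs *within mouse* (preserving the random-effect
structure; a global shuffle is available) and refits; the empirical p is
the fraction of |null| ≥ |observed|.

## Estimation machinery

Mean differences are reported with percentile-bootstrap CIs (default 5,000
resamples; pairs resampled jointly when paired) and two-sided permutation
p-values. Monte Carlo permutation p uses the add-one convention
`(1 + #extreme)/(1 + n_perm)` so p is never exactly zero; when the paired
sign-flip space 2ⁿ fits within the requested permutation count it is
enumerated exhaustively and the exact p returned. The same default count
(5,000) is used for bootstrap and permutation.

## Synthetic study conditions

The generator defines the conditions under which every stage is verified:

* 1250 Hz laminar LFP; 64 channels by default (32 or 16 where the laminar
  profile is not under test). Background = per-channel 1/f (pink) noise
  plus a weak common 2 Hz delta, smoothed across the depth axis (σ = 1.5
  channels — real laminar LFP is spatially correlated) and renormalized to
  unit median absolute value per channel, so `event_amp` is expressed
  directly in the detectors' threshold units.
* DS at 0.40 Hz and SWR at 0.75 Hz in sleep segments (durations drawn
  40–50 ms; events thinned to ≥ 150 ms separation so ground truth stays
  unambiguous); DS₁ fraction 0.35. `event_amp = 8` (vs the 6×MAD DS and
  5×median-envelope SWR thresholds).
* The DS laminar profile is planted as a compact Gaussian LFP dip at the
  per-type sink depth (outer molecular for DS₁, inner for DS₂) — its
  discrete second difference *is* a central sink with flanking sources,
  so CSD recovers the planted depth without approximation — plus a linear
  depth ramp (zero second difference, hence CSD-silent) pinning the
  granule-layer detection amplitude exactly.
* SWRs: a 150 Hz ripple under a Gaussian envelope (≥ 6 cycles) on
  pyramidal channels riding a negative radiatum deflection; exploration
  segments carry ~8 Hz theta with slow phase drift, strongest near
  lacunosum-moleculare.
* Spikes are inhomogeneous Poisson by superposition: baseline rates
  (principal 1.2 Hz, interneuron 8 Hz, log-normal spread) plus
  event-locked extra spikes concentrated around the event peak, with
  multiplicative gains per region × event type (DG strongest in DS,
  DS₂ > DS₁; CA strongest in SWR). Pairwise couplings are planted through
  a shared Bernoulli latent per event window (probability = weight) that
  adds synchronous spikes to both cells — interpretable ground truth for
  β recovery. A `reactivation_gain` carries selected theta couplings into
  post-sleep event windows only.
* Trajectories are Ornstein–Uhlenbeck random walks at 25 Hz confined to a
  41 × 41 cm arena; place fields are Gaussian (σ = 5 cm, peak 15 Hz —
  chosen so a field unit clears ~0.7 bits/spike over a 10-minute walk
  while uniform units stay near zero).
* Waveform templates are biphasic with trough-to-peak widths from the
  classic bimodal mixture (narrow ≈ 0.2 ms interneurons, wide ≈ 0.6 ms
  principal cells) and strictly positive per-sample s.d.
* The granule-layer waveform epochs for the typing discriminant use two
  fixed templates with 50 Hz low-passed noise scaled so the class
  separation along the template-difference direction is 2.8 Mahalanobis
  units (Bayes accuracy ≈ 0.92) — fixed by construction, not tuned.
* Coefficient-level generators (`coupled_count_matrix`,
  `reactivation_pair_table`) plant linear couplings and the transfer
  structure `post = a·theta + b·pre + mouse + noise` directly, with
  defaults a = 0.3, b = 0.2, mouse s.d. 0.25, noise s.d. 0.3 over 4 mice
  × 150 pairs.

**What the generator does not emulate:** biophysical membrane currents,
sleep-state scoring, EMG, spike-sorting errors, electrode drift, behavioral
state transitions, or theta phase precession. Passing tests show the
pipeline recovers exactly what it claims to measure under its stated
assumptions; they do not certify performance on recordings whose noise or
event morphology departs strongly from these conditions.

## Problem sizes

Verification uses 600 s sessions (5 seeds) for detector recovery, one
300 s 64-channel session (~180 DS events) for CSD typing, 600 waveform
epochs for the discriminant, 400–600 event windows for population and
coactivity statistics, 600 cell pairs for reactivation recovery, and 200
reduced runs (19 shuffles each — an exact 1/20-level test) for the
shuffle-null calibration. These sizes put Monte Carlo noise well inside
the asserted tolerances while keeping the default suite fast.

## Known limitations

* Detected SWR durations (half-threshold envelope crossings of a Gaussian
  envelope) run ~60–70 ms, longer than the planted 40–50 ms core — the
  envelope definition, not a detector fault.
* The Onnela normalization by the maximum signed weight is undefined for
  all-non-positive graphs; the module raises there by design.
* `MixedLM` variance components often sit on the zero boundary for small
  mouse counts; the result flags this but keeps the fixed effects.
* The masked-sift theta path, like empirical-mode methods generally,
  yields theta-frequency components for broadband noise; cycle statistics
  are only meaningful within identified theta epochs.
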