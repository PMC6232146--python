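# Methods

This note documents the models, the numerical choices and the limits of
what the synthetic validation can show.

## Pipeline model

One subject's session is a contiguous sequence of 15-s trials (fixation
3 s, observation 4 s, execution 4 s, relaxation 4 s), all repetitions of a
condition presented consecutively in one block, block order a seeded
permutation.  The analysis chain per subject:

1. **EEG conditioning.**  Butterworth fourth-order zero-phase band-pass
   0.1–40 Hz, decimation to 100 Hz (only exercised when the generator is
   asked for 1-kHz raw EEG; the default synthesizes at 100 Hz directly, a
   runtime choice with no loss for band-limited synthetic signals).
2. **Epoching** into 15-s trials relative to each trial start, reordered
   to a common ascending condition order.  Incomplete trials are flagged.
3. **Movement onset** from the accelerometer magnitude: within the first
   second after the execute cue, the split point of a two-segment
   piecewise-linear (mean + slope) fit that minimizes the total squared
   residual, accepted when it improves on the unsplit fit by ≥ 10%
   (minimum segment 5 samples).  This is an exhaustive scan over split
   points, computed in closed form from prefix sums; a tie (a change point
   lying on both segment lines) resolves to the earliest split.
4. **Trial rejection.**  (a) Movement during observation: the smoothed
   (100-ms moving average) accelerometer magnitude deviates from the
   fixation-baseline mean by more than 5 baseline SDs *continuously for at
   least 200 ms*.  The duration requirement exists because a max-statistic
   over ~200 samples routinely exceeds 5 SD by chance for a single sample,
   while genuine movement bursts are sustained.  (b) Tracking glitch: any
   single-step joint-angle jump above 60° (wrapped difference).  All
   thresholds are configurable; a condition losing all trials is flagged
   unusable and the run fails loudly.
5. **ERD/S.**  Morlet wavelet power on a 0.5-Hz grid, 0.5–40 Hz (80 bins —
   the 0.1-Hz band edge lies below the first representable 0.5-Hz-step bin
   center), wavelet width increasing linearly 3 → 8 cycles across the
   grid, Gaussian envelope truncated at ±3.5 SD.  Bins whose wavelet
   exceeds the epoch are flagged invalid, never silently zero-padded.
   Implementation: FFT convolution with per-frequency FFT sizes, grouped
   so each forward transform is reused; an independent implementation
   (mne) serves as a cross-check in the tests.  The baseline is the
   subject-level mean power over the fixation interval 1–3 s of all kept
   trials; ERD/S = (P_movement − P_baseline)/P_baseline × 100%, no
   clipping.
6. **EMG envelope.**  Per-channel z-score over the *session*, then the
   magnitude of the analytic signal.  Standardizing per trial would divide
   each channel by its own trial RMS — which removes exactly the
   between-condition amplitude differences that an amplitude-coded synergy
   model produces; session-level standardization preserves them.  The
   order (standardize → analytic-signal magnitude) is fixed and recorded
   here because the usual verbal description of the chain is ambiguous.
7. **Kinematics.**  Cubic-spline interpolation of the irregular 80–120 Hz
   joint streams onto a 100-Hz grid (splining unwrapped angles, re-wrapping
   to (−π, π]); per-subject PCA retaining 5 components; repetitions are
   averaged with the circular mean *before* projection onto the subject's
   components.  For group averaging, each subject's components are aligned
   to the first subject's by greedy maximal-|cosine| matching with sign
   flips — PCA bases are only defined up to order and sign, and some
   convention is required to make them commensurable; this one is the
   simplest that is exact when subjects share a basis.
8. **Windows and patterns.**  Three consecutive 500-ms windows from the
   detected onset.  EEG patterns concatenate ERD/S over one searchlight
   cell (5 channels × 5 bins × 50 samples = 1250 values, channel-major);
   EMG patterns concatenate 8 envelope channels × 100 samples; kinematic
   patterns 5 component trajectories × 50 samples.
9. **RDMs and comparisons.**  1 − Pearson distances; off-diagonal entries
   rank-transformed (average ranks for ties) and min–max scaled to [0, 1];
   the raw matrix is retained.  RDM-to-RDM distance is 1 − Spearman ρ over
   the 528 lower-triangle entries — invariant to any monotone transform of
   either matrix, so comparing rank-scaled or raw matrices is equivalent.
   A constant matrix (e.g. a categorical scheme collapsing to a single
   category on a reduced condition set) has no rank structure; its
   distance to anything is defined as 1.
10. **Bootstrap.**  Subjects are resampled with replacement (never trials);
    each iteration recomputes group patterns → region RDMs → region-mean
    distance to the candidate; the CI is the percentile interval.  CI
    violations of the observed value are flagged, not hidden.
11. **Second level.**  The pairwise 1 − Spearman matrix among the region
    EEG RDM, the EMG and kinematic RDMs and the three categorical models,
    per window.

## Searchlight layout

Frequency neighborhoods are fully determined by the counting constraints:
5 consecutive bins, consecutive neighborhoods sharing 2, hence stride
3 bins (1.5 Hz) and (80 − 5)/3 + 1 = 26 neighborhoods, each spanning 2 Hz.
The channel space is under-determined: the original 31 centroids are not
recoverable from published information.  The shipped layout orders the 61
channels of the 10-10 montage periphery-to-midline (left to right) and
anterior-to-posterior within each sagittal column, then chains
neighborhoods along this traversal with stride 3 (wrapping), which
guarantees exactly the 5-member / 2-shared invariants; it is frozen as a
versioned JSON file so results are reproducible, and any user layout is
validated against the same invariants at load time.

## Synthetic data: what it emulates, and what not

The generator plants ground truth at every level the pipeline measures:

* **EEG:** 1/f-weighted background noise plus ongoing 10-Hz and 30-Hz
  rhythms with random phase (condition-independent).  On the five channels
  of the target neighborhood, five oscillators at the target band's bin
  frequencies — amplitude peaking at the band center — are suppressed
  during execution (smooth 150-ms ramps from the movement onset) by
  condition-specific depths.  Depths are `erd_depth` (default 0.5) plus an
  effect-size-scaled random projection of the classical-scaling embedding
  of a model RDM, clipped to [0.05, 0.95]; at `effect_size = 0` all
  conditions are exchangeable by construction.
* **EMG:** per-channel amplitude `rest + (weights @ activations) ·
  profile(t)` modulating a white-noise carrier; condition similarity of
  the envelopes follows the similarity of the activation vectors.
* **Joint angles:** `rest + basis @ (scores · profile(t))` plus angular
  noise, wrapped to (−π, π], sampled at timestamps with spacing uniform in
  [1/120, 1/80] s.
* **Accelerometer:** quiescent noise with, at each onset, an abrupt
  mean-and-slope change that stays exactly piecewise-linear throughout the
  one-second detection window, so noiseless detection is exact and
  ground-truth onsets are returned.  Onset latency defaults to 300 ms
  after the execute cue, jittered and clipped into (20 ms, 980 ms).
* **Bad trials:** observation-phase accelerometer/EMG bursts and
  joint-angle discontinuities, injectable per trial, for round-trip tests
  of the rejection rules.

Default SNR regime: `noise_sd = 2.0`, `osc_amplitude = 1.2`,
`effect_size = 1` ("large" in validation runs: 3).  Frequency localization
of a planted effect is limited by the Morlet bandwidth σ_f ≈ f/cycles:
because correlation distance is scale-invariant, a cell receiving even a
weak spectral leak of the modulated rhythm reproduces the model RDM
unless background noise masks it.  The default regime places the noise so
that leakage beyond ±1 frequency neighborhood (±1.5 Hz) falls below it —
at mu-band frequencies this localizes the arg-min to the planted cell or
an overlapping neighbor; around 20 Hz and above, wavelets are broad
enough (σ_f ≳ 3 Hz) that a several-cell plateau is physically unavoidable.
The default planted cell is therefore the left centro-parietal
neighborhood (centroid CP3) × 9.5–11.5 Hz.

The generator does not emulate: eye/ECG artifacts (cleaning is an identity
hook), volume conduction between channels, 1/f slope variability, real
muscle-tremor spectra, inter-subject montage differences, or any claim
about the real study's effect sizes.  Passing the recovery tests shows the
*pipeline* is correct and sensitive in a controlled regime; it says
nothing about effect sizes in real recordings.

## Validation design choices

* **Change-point oracle:** the detector is compared against an exhaustive
  brute-force implementation (explicit polynomial fits) on noiseless
  piecewise-linear signals up to length 200, and must recover 100% of
  onsets on noiseless accelerometer sessions.
* **RDM oracles:** explicit-loop Pearson distances, manual average ranks
  and rank-scaling, and a manual Spearman distance, matched to 1e-12 on
  random 6-condition instances.
* **Planted-effect recovery:** 20 seeded end-to-end runs at reduced scale
  (5 subjects, 1 repetition per condition, 33 conditions — chosen so a
  full run takes ~25 s on one CPU); the arg-min cell must fall in the
  planted cell's overlap set (cells sharing ≥ 1 channel and ≥ 1 bin) in
  ≥ 90% of runs, and the object-shape model must be the first window's
  best candidate at the planted region.
* **Bootstrap calibration:** percentile CIs are validated on a population
  in which each subject mixes a second representational structure with a
  random weight (plus i.i.d. pattern noise).  This places the statistic in
  the first-order regime the percentile bootstrap assumes.  Two designs
  that look natural but break the calibration are documented here as
  warnings: pure i.i.d. pattern noise makes the group statistic vary only
  at second order (the CI then measures bias, not sampling variance), and
  a *binary* candidate RDM gives the rank statistic plateaus (the distance
  is piecewise-constant in the mixing weight).  The expected population
  distance is computed by direct Monte Carlo, independent of the bootstrap
  machinery, and coverage over 200 outer runs must lie in [0.90, 1.00].

## Known limitations

* The channel-neighborhood layout is a reproducible convention, not the
  original study's (unrecoverable) centroids; "four equidistant neighbors"
  is approximated by traversal adjacency on the montage.
* Whether PCA precedes or follows circular-mean averaging of repetitions
  is not fully determined by the verbal description of the original chain;
  this pipeline averages angles first and projects second, and flags the
  choice as an interpretation.
* The empirical effect values of the original study (dissimilarities
  ~0.8/0.68 with their CIs) require the real 31-subject recordings and are
  out of reach of synthetic validation; the package reproduces the
  machinery and its structural guarantees, not those numbers.
* Runtime: the Morlet stage dominates (~4.5 s per subject per 33 trials at
  100 Hz); full-scale sessions (8 repetitions, 31 subjects) are feasible
  but take tens of minutes on one CPU.
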