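# Methods

This note documents the models, parameter choices and numerical decisions
behind `attnmark`, and what the synthetic-data checks do and do not
establish about real recordings.

## The analysis chain

### Preprocessing

Continuous recordings are band-pass filtered with a zero-phase 4th-order
Butterworth (0.5–30 Hz by default), applied forward–backward so the
effective magnitude response is the squared single-pass response and no
phase distortion is introduced. Filtering precedes re-referencing to the
average of the two mastoid channels (M1, M2); the re-reference is guarded
against double application. Artifact rejection is a deterministic
peak-to-peak threshold on epoched data (200 μV default, any channel):
manual drift screening and ICA-based blink correction are interactive,
non-deterministic procedures that cannot be meaningfully validated on
synthetic blink-free data, so a reproducible amplitude criterion stands
in their place; the threshold is configurable. Flagged epochs are kept in
the container, only marked, so rejection is lossless and auditable.

### Spectral markers

Resting epochs are 1000 ms, cut contiguously inside each eye-condition
block so no epoch straddles a boundary (block durations must be whole
multiples of the epoch length). The Welch estimate treats each epoch as
one segment: mean removal, Hamming taper, zero-padding from 1000 to 1024
points, density-scaled periodogram with taper-power correction, averaged
over retained epochs. The 1024-point grid at 1000 Hz gives the 0.9766 Hz
resolution of the analysis recipe; zero-padding to a power of two is the
only reading consistent with that figure for one-second epochs. Phase is
discarded (magnitude-only spectra).

Band powers are rectangle integrals — the sum of density over bins whose
center falls in the half-open interval [low, high), times the grid
spacing — so 8 Hz belongs to alpha and 13 Hz to beta and no bin is
counted twice. Absolute powers are in μV². The theta/beta ratio is the
exact quotient of band powers; the square-root transform is applied after
epoch averaging, per electrode and condition, before any correlation.

### ERP quantification

Stimulus-locked epochs span [−200, 1000) ms (1200 samples at 1000 Hz).
Baseline correction subtracts the per-epoch, per-channel mean over
[−200, 0) ms. Incorrect-response trials and artifact-flagged epochs are
removed before averaging; RT summaries likewise use correct trials only
(the field convention — error-trial RTs reflect a different process).
Component amplitudes are signed means over inclusive windows on the
sample grid (N2: Fz, 230–380 ms → samples 430..580; P3: CPz,
400–600 ms); "negative mean amplitude" is read as the signed mean, which
is negative for N2, not a rectified magnitude. Difference scores are
incongruent − congruent for N2d, P3d and RT interference.

### Inference

* Paired t: t = mean(d)/(sd(d)/√n) with the n−1 standard deviation,
  df = n−1, two-tailed p from the central t distribution, Cohen's
  d = mean(d)/sd(d) ≡ t/√n (an identity the tests verify to machine
  precision).
* Pearson r: two-tailed p via the exact transform t = r√(n−2)/√(1−r²),
  df = n−2. Perfectly collinear input (|r| within 1e-12 of 1) is reported
  as r = ±1 with p = 0. Cells with n < 3 are reported with p = NaN.
* Correlation power: the test statistic under ρ ≠ 0 is approximated as
  noncentral t with df = n−2 and noncentrality ρ√n/√(1−ρ²); power is the
  two-sided tail mass beyond the central-t critical value, and the
  minimal sample size is the first n ≥ 4 reaching the target in an
  upward scan. This reproduces n = 45 for ρ = 0.395 at α = 0.05, power
  0.8. The approximation is anchored by simulation at the design point
  (empirical rejection rate at ρ = 0.395, n = 45 matches the analytic
  power within Monte-Carlo error); at very small n with large ρ it is
  optimistic — e.g. it returns n = 5 for ρ = 0.9 where the empirical
  power is ≈ 0.67 rather than 0.8 — which is a property of the method,
  not of the implementation.
* No multiple-comparison correction is applied by default, matching the
  analysis being emulated; Bonferroni and Benjamini–Hochberg switches
  exist on the report builder.

## The synthetic cohort

The generator's defaults encode the emulated study conditions: 58
subjects; 8 minutes of resting EEG in alternating 60 s eyes-open /
eyes-closed blocks (eyes-open first — the original protocol does not
state the order); 120 flanker trials per condition with fixation 300 ms,
blank 1200–1600 ms, stimulus 200 ms, inter-trial interval 2000–2400 ms;
1000 Hz sampling; a six-channel montage (Fz, Cz, Pz, CPz, M1, M2) — the
only channels any analysis stage touches.

### Latent structure

Five subject-level measures (ACS total, theta/beta ratio, eyes-open
alpha power, RT interference, P3d) follow a Gaussian copula: a standard
normal vector is drawn per subject, multiplied by the Cholesky factor of
the target correlation matrix (validated positive semi-definite at
construction; on failure, the error names the pairs whose removal
restores PSD), and pushed through marginal maps. The ACS marginal maps
the latent normal through its CDF onto integers 20–80; the others are
affine maps with occasional clipping far in the tails. Marginal anchors
come from the group statistics of the kind of cohort being emulated
(means ± between-subject SDs): √TBR 2.33 ± 0.53, √alpha(open)
1.97 ± 0.60, alpha reactivity 2.05 ± 0.25 (amplitude factor, floor 1),
congruent RT 466 ± 80 ms, RT interference 62.4 ± 22.9 ms, congruent
accuracy 0.976 ± 0.053 with a paired decrement of 0.051 ± 0.088, N2
−1.54 ± 4.80 μV with N2d −1.05 ± 1.78 μV, P3 6.23 ± 4.04 μV with P3d
1.07 ± 2.61 μV. The between-subject SDs are the printed standard errors
scaled by √58. The nonlinear marginal maps attenuate the realized
Pearson correlations by a few percent relative to the copula targets
(the CDF map alone contributes a factor ≈ 0.977); this is well inside
the Fisher-z recovery band the tests check.

The default target-correlation matrix carries the emulated study's
headline pairs (ACS–TBR −0.263, ACS–RT 0.305, ACS–P3d 0.152, ACS–alpha
−0.131, alpha–RT −0.266, alpha–P3d 0.285, RT–P3d −0.261); unstated pairs
are zero. Seeding is hierarchical — `SeedSequence(seed, spawn_key=
(subject, stage))` — so enlarging a cohort never perturbs existing
subjects, and identical (spec, seed) reproduces everything bitwise.

### Signals

Background noise is 1/f-power Gaussian noise (flat below 0.5 Hz, no DC),
2 μV RMS nominal with ±15 % lognormal between-subject variation,
independent per channel; mastoids carry it at half scale and no
oscillatory signal, so the average-mastoid re-reference cannot cancel
the signals of interest. Rhythms are coherent across the four scalp
channels. Two realizations are available:

* `narrowband` (default): complex Gaussian spectra shaped by the
  magnitude response of a 4th-order Butterworth band-pass at the band
  edges (theta 4–8, alpha 8–13, beta 13–30 Hz) — equivalent to filtering
  white noise, but synthesized spectrally in one batched inverse FFT.
  Each carrier is scaled so its power inside its own band's bins is
  exactly A²/2 for profile amplitude A (Parseval, computed in closed
  form before the inverse transform). Filter skirts put a few percent of
  additional power into neighboring bands; that cross-talk is physically
  realistic and left in.
* `sinusoid`: pure tones at 6/10/20 Hz with random phase, for analytic
  tests — a tone of amplitude A has variance exactly A²/2.

While the eyes are closed the alpha carrier is multiplied by the
subject's reactivity factor, so eyes-closed alpha band power is exactly
reactivity² times eyes-open power for tonal carriers and so in
distribution for narrowband ones. Oscillatory beta band power is
anchored at 2 μV² (±15 % lognormal) and theta power is the subject's
latent TBR times it.

Flanker recordings add calibrated stimulus-locked templates to the
ongoing background: Gaussian bumps (N2 peak 300 ms, SD 40 ms, frontal
weighting maximal at Fz; P3 peak 500 ms, SD 60 ms, centro-parietal
weighting maximal at CPz), each normalized to unit mean over its own
measurement window. Because the two bumps bleed slightly into each
other's windows, amplitudes are injected through the inverse of the 2×2
cross-talk matrix, making the noise-free measured window means equal the
profile targets exactly (the tests verify < 1e-6 μV). RTs are truncated
normal (> 150 ms, within-subject SD 60 ms); correctness is Bernoulli per
condition. Trial-condition order is a random permutation with exact
50/50 counts. Flanker recording lengths are rounded up to a 32 s grid so
spectral-shaping tables are shared across subjects; the tail carries no
trials.

### What the generator does not emulate

No eye blinks, electrode drift, line noise, volume conduction, 1/f slope
variation, alpha peak-frequency variation, RT/accuracy speed–accuracy
coupling, or fatigue effects. Passing tests therefore demonstrate that
the analysis chain is correct and unbiased under a clean generative
model with the right covariance structure — not that it is robust to the
artifacts of real EEG, which the deterministic amplitude-threshold
rejection only crudely addresses.

## Numerical choices

* EDF on disk: 16-bit, one-second records, symmetric physical range
  chosen per file from the data, so quantization error is bounded by
  range/2¹⁶; events in a tab-separated sidecar (0-based onset samples,
  half-open spans) because EDF+ annotation dialects do not round-trip
  reliably. The writer and reader are this package's own minimal
  implementation; an independent reader (MNE) verifies the writer in the
  test suite.
* Filtering stays in float64: at a 0.5 Hz corner and 1000 Hz sampling,
  single precision loses ~3 significant digits.
* Degenerate inputs fail loudly: zero-variance t tests, all-rejected
  epoch sets, emptied conditions after trial removal, bands outside the
  spectral grid, double re-referencing.
* Report tables round to 3 decimals; the inter-measure table shows the
  lower triangle with an em dash on the diagonal.

## Problem sizes used in the checks

The seed-replicated correlation-recovery check runs 100 seeds × 58
subjects with a 2-minute resting arm (four alternating blocks) per
subject: the quantity under test — the between-subject correlation of
ACS with measured eyes-open frontal √TBR — is insensitive to recording
length once the within-subject spectral estimate is stable (60 epochs
per condition), and the shorter arm keeps the 100-replicate sweep
tractable. The group-level direction checks (RT, accuracy, N2, P3
condition effects; eyes-closed > eyes-open alpha) run one full-default
58-subject cohort. Most unit tests use 2-minute recordings and 8–12
trials per condition.

## Known limitations

* The ACS item-level keying is synthetic: item responses are generated
  to be consistent with a target total under a configurable reverse-key
  set, and scoring with the same set round-trips exactly. Real
  scale-version keying must be supplied by the user.
* "Absolute power" is implemented as the epoch-averaged density
  integral; analyses that depend on a per-epoch power sum convention
  would differ by a constant factor (correlations and orderings are
  unaffected).
* The noncentral-t power approximation is optimistic for large ρ at
  very small n (see above).
* The eyes-closed theta/beta ratio is not separately manipulated by the
  generator: the eye-condition contrast it produces for TBR is small and
  alpha-leakage-driven, unlike the alpha contrast, which is explicit and
  large.
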