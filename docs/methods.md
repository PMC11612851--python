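# Methods

This note documents the models implemented in `melodic_trf`, the
assumptions of the synthetic-data generator, and the numerical design
decisions, in the order the pipeline applies them.

## Information-theoretic stimulus model

Melodic expectation is quantified per note by two quantities derived from
a note-probability model: surprisal `S(e_i) = log2 1/p(e_i | e_1..i−1)`
(how unexpected the realized note is — a prediction-error proxy) and
entropy `H = Σ_e p(e | context) · log2 1/p(e | context)` (how uncertain
the continuation is — a prediction-uncertainty proxy). Both are computed
separately for the **timing** stream (inter-onset intervals, columns
`Ho`/`So`) and the **pitch** stream (columns `Hp`/`Sp`).

The probability model is pluggable. The shipped stand-in is a first-order
Markov model: an order-k chain over a MIDI pitch alphabet (contexts
shorter than k fall back to an initial distribution) and an independent
first-order chain over a small set of discrete inter-onset-interval (IOI)
categories. Because the generator and the scorer are the same object, the
information values are exact — no estimation error — which is what makes
kernel-recovery experiments well-posed. The stand-in makes no claim of
equivalence to trained variable-order models (IDyOM-style); it exists so
that downstream machinery can be validated against known ground truth.
A realized event with model probability zero (e.g. an IOI that matches no
category) is rejected with a diagnostic rather than mapped to infinite
surprisal.

### Generator defaults

* 20 subjects (half labelled `musician`), 10 melodies of ~150 s presented
  3 times (30 trials), 64 channels at 512 Hz — the shape of the kind of
  listening experiment the pipeline targets. Small cohorts for tests
  override these fields explicitly.
* Pitch alphabet: 12 semitones from MIDI 60; Dirichlet(0.3) transition
  rows (peaky, hence a wide dynamic range of surprisal across notes).
* IOI categories (0.2, 0.4, 0.6, 0.8) s with Dirichlet(0.8) transitions:
  ~2.5–3 notes/s, a typical solo-piano event rate.
* Note velocities ~ Uniform(0.4, 1): piano dynamics. This also matters
  statistically — with constant velocities the envelope is an exact
  linear-time-invariant function of the onset train and envelope/onset
  kernels would not be separately identifiable.
* Envelope surrogate: per note, a velocity-scaled mix of a fast (50 ms)
  and a slow (400 ms) exponential decay gated to the note duration, the
  mix depending on pitch class. The profile peaks at onset. The mix
  variation again serves identifiability (envelope vs its derivative).
  No audio is synthesized; `envelope_from_waveform` (Hilbert magnitude +
  anti-aliased resampling) covers real WAV input.
* EEG forward model: channel c receives
  `Σ_f gain_f[c] · (s_f ⊛ k_f) + noise`, with per-feature Gaussian-blob
  topography gains over a synthetic sunflower-layout 64-electrode cap
  (mastoids M1/M2 outside the head outline). Noise is pink (1/f, 80% of
  noise variance) plus white, scaled so that `snr` = mean per-channel
  signal SD / noise SD. Noise is reproducible from
  (cohort seed, subject, trial); topographies depend only on the cohort
  seed, so group-level effects are spatially coherent.
* Band-specific simulation: with a band tag, the recording *is* that
  band's signal; without one, each band's kernel contribution is filtered
  into its frequency range and summed into a broadband recording for the
  full preprocessing pipeline.

### What the generator does not emulate

Eye/muscle artifacts, electrode drift and re-referencing artifacts,
nonlinear or adaptive neural responses, between-subject latency and
topography variability, and the statistics of real Western tonal music.
Passing tests therefore demonstrate that the *estimation machinery* is
correct and calibrated under the stated noise model — not that any
scientific claim holds on real EEG.

## Feature matrices

Impulse-type regressors (onset, pitch, information values) are built
directly at the 64 Hz analysis rate — onset sample = round(onset·fs),
ties to even, 0-based — rather than at audio rate and decimated, which
would alias impulses. Collisions (two notes on one sample) keep a single
1 in `O` and the later note's value in `P`. Information columns are used
unstandardized by default; `standardize_information` optionally z-scores
their nonzero entries (zeros untouched). Standardization is the
recommended setting for simulation studies: it makes the information
regressor orthogonal to the onset train, so an "information effect" can
not be mimicked by onset timing alone. The planted-effect experiments in
`validation.py` use it for exactly that reason.

## Preprocessing

Fixed order, each step appended to a provenance log: band filter →
bad-channel detection/interpolation → mastoid re-reference → (Hilbert
amplitude + 0.5–20 Hz post-filter for all bands except delta and low) →
downsample to 64 Hz.

* Filters: 2nd-order Butterworth applied forward-backward
  (`sosfiltfilt`), i.e. zero-phase with effective order 4.
* Bad channels: SD over the full recording strictly greater than 3× the
  mean SD of all other channels; single pass, no iteration.
* Interpolation: normalized inverse-squared-distance weights over the 2-D
  layout. Spherical splines would be marginally smoother but need a 3-D
  head model; the distance-weighted scheme is fully specified, testable
  by symmetry, and adequate for synthetic layouts. The method is a
  pluggable function.
* Hilbert amplitude via the frequency-domain analytic signal on the whole
  trial. The first and last second of every trial are excluded from
  accuracy computations to avoid filter and convolution edge artifacts.
* Downsampling: polyphase anti-aliased resampling (512 → 64 Hz is the 1/8
  branch). Filtering is applied per trial; applying it to a continuous
  recording before epoching would differ only at trial boundaries, which
  the edge exclusion already discards.
* The gamma band is implemented and tested but treated as an expected
  null: scalp EEG at 30–48 Hz carries little stimulus-locked variance.

## TRF estimation

* Lag window −150 … 750 ms (at 64 Hz: lags −10 … 48, 59 samples).
  Positive lag = response follows stimulus; negative lags carry
  anticipatory weights.
* Ridge solution `(SᵀS + λD)⁻¹Sᵀr` with `D` the identity except a zero
  for the intercept (the offset should not be shrunk). λ is multiplied by
  trace(SᵀS)/p of the penalized block, which makes the printed grid
  dimensionless across feature scalings; raw λ is a switch.
* λ grid: 13 powers of ten, 10⁻⁶ … 10⁶.
* Nested leave-one-out CV over trials: the outer fold holds out one
  trial; the inner loop scores each λ by channel-mean held-out r averaged
  over inner folds; ties break toward the smaller λ (deterministic).
  The outer model is refit on all training trials at the selected λ,
  yielding one weight set and one per-channel r per fold. Per-channel
  accuracies are averaged over folds before entering group statistics.
* Solves use Cholesky factorization on per-trial Gram matrices summed per
  training set, so leave-one-out training sets are O(p²) updates; a
  singular system at λ=0 falls back to a minimum-norm least-squares
  solution rather than crashing.

## Model ledger

The acoustic baseline `A` is {Env, EnvD}; the onset and pitch vectors can
be added via `include_onset_pitch` (both compositions are defensible —
the onset/pitch vectors are acoustic-adjacent but already carry melodic
timing information; keeping them out of the default `A` makes the
baseline purely acoustic, and the switch makes the other reading one flag
away). The ledger comprises `A`, the four single-feature `AF` models, the
four `AM−F` models, the combined `AMo`, `AMp`, `AH`, `AS`, the full `AM`,
and `AM-shuffled` (15 specs). The shuffled control permutes each
information column's nonzero values among its own nonzero positions —
onset structure and value distribution preserved, assignment destroyed —
with one realization per seed (repetitions configurable). `AM-shuffled`
runs the full nested CV, re-selecting λ like any other model.

## Group statistics

* Wilcoxon signed-rank: midranks for ties, tie-corrected normal
  approximation, no continuity correction, zero differences dropped and
  counted. Effect size is **z/√n**: its analytic ceiling for unanimous
  differences is 0.8765 at n=20 and 0.8864 at n=10, the values a
  one-sided test reports for a unanimously positive contrast at those
  cohort sizes (z divided by n itself could never reach such values).
* Electrode clusters: per-electrode signed-rank z, two-sided cluster-
  forming threshold p < .05, clusters connected in a Delaunay adjacency
  of the 2-D layout with edges > 1.5× median length pruned (this keeps
  mastoids from bridging across the head), cluster mass = Σz, null =
  maximal |mass| under subject-level sign flips, corrected
  p = (1 + #{null ≥ obs}) / (1 + n_perm). Sign flipping at the subject
  level is the standard exchangeability unit for a within-subject
  contrast.
* TRF-weight testing: channel-averaged weights over the electrodes
  selected by the cluster test (all channels if none), smoothed with a
  unit-sum 100 ms Hamming window (forced odd length, 7 samples at 64 Hz),
  then a sign-flip permutation test with 1-D TFCE along the lag axis
  (E=0.5, H=2, dh = max|t|/100 — the field's usual defaults), two-sided
  via separate enhancement of the positive and negative parts.
  Significant lags merge into contiguous windows.
* Peak latency: argmax of |smoothed weight| within a window, ties (and
  all-zero windows) resolve to the earliest lag and are flagged;
  latencies compared across features with the two-sided signed-rank test.

## Validation experiment sizes

The standing studies in `validation.py` (run by `scripts/acceptance.py`
and the test suite) use: 50 random instances for the ridge/OLS oracle;
a 5-subject × 6-trial × 30-s × 16-channel cohort at SNR 10 for kernel
recovery and enhancement contrasts (kernel estimates are projected onto
the known topography gains across channels before correlating with the
planted kernels, pooling channel information instead of reading a single
electrode); 200 null cohorts (20 subjects × 16 electrodes, 1,000
permutations) for cluster-test calibration; and 100 cohorts with a 150 ms
bump at per-lag Cohen's d = 1.5 (500 permutations) for TFCE power. These
sizes give stable pass/fail behaviour in minutes on one CPU; the
estimators themselves scale unchanged to full experiment sizes.

## Known limitations

* The Markov stand-in's entropy range is narrow compared with trained
  melodic models; unstandardized information regressors are therefore
  strongly collinear with the onset train (see the standardization note
  above). This mirrors a real property of such regressors, which is why
  the shuffled control and the unique-contribution metric exist.
* Inverse-distance interpolation ignores scalp curvature.
* The cluster test's per-electrode statistic is the signed-rank z; a
  paired t is available as a switch but not the default.
* Linear mixed-effects comparisons across bands/features are out of
  scope; the `ComparisonTable` TSV is the tidy input such an analysis
  would consume.
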