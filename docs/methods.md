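# Methods and design notes

## The identification model

A person's steady-state visual evoked response is treated as a set of
stationary cortical sources oscillating at the stimulation frequency and its
harmonics, mixed linearly onto the electrodes.  Identity lives in the mixing:
two viewers of the same flicker produce the same spectral content with
different channel-space geometry.  Filterbank common spatial patterns (one
CSP problem per person against the pooled rest, per frequency band) recover
filters aligned with each person's pattern; the log-variance of each
spatially filtered trial is near-Gaussian and scale-compressed, which is why
it is the canonical CSP feature.  The deep feedforward network then learns a
non-linear re-representation of those features; its first block deliberately
*expands* the dimension (a kernel-trick-style lift) before two contracting
blocks encode it.

## Synthetic data generator

`ssvepid.synthetic` emulates exactly the ingredients the pipeline is
sensitive to:

- **Narrowband structure** — each source emits Σ_h a_h·sin(2π·h·f·t + φ_h)
  with H = 3 harmonics at amplitudes (1, 0.5, 0.25), the typical SSVEP
  roll-off (≈ −6 dB per harmonic).  Phases are drawn per subject; multiple
  sources are decorrelated by fixed per-source phase lags.
- **Subject-specific spatial mixing** — an Nch × n_sources matrix with
  unit-norm Gaussian columns per subject.  A single `subject_separation`
  knob interpolates every subject's columns spherically toward one shared
  base matrix: 0 = independent patterns (easy), 1 = identical patterns
  (identification is impossible by construction, the chance-level null).
- **Broadband noise** — white, or the default equal-power white + 1/f
  mixture (raw EEG is dominated by 1/f background).  Noise is scaled so the
  realized ratio of projected-source power to noise power matches `snr_db`
  (contract: within 1 dB).
- **Determinism** — random streams are split per (subject, block, frequency)
  from one seed via `SeedSequence`, so the trial set is a pure function of
  its config and growing the design never changes existing trials.

What it does **not** emulate: volume-conduction head geometry, eye-blink and
EMG artifacts, inter-block non-stationarity (electrode drift, fatigue),
latency jitter, and phase-coded stimulation.  Passing tests on this
generator therefore demonstrate that the pipeline recovers identity *when it
is encoded purely in stationary spatial patterns* — the mechanism the method
targets — not that it is robust to every nuisance in recorded EEG.

Default conditions: 10 subjects × 6 blocks, one stimulation frequency,
250 Hz sampling, 5 s trials, 9 channels, 2 sources, 10 dB SNR.

## Preprocessing

- 4th-order Butterworth band-pass applied forward-backward (zero phase,
  effective order 8); the maximally flat IIR family is the conventional
  choice.  Edge handling: odd-reflection padding of length 3·(order+1)
  samples; trials shorter than the padding are rejected.
- Pipeline order is fixed FILTER → WINDOW: the full-length trial is
  filtered, then cut to the analysis window TW, so short windows carry no
  filter edge transients.  Window onset defaults to 0 s (stimulus-locked
  trials); it is configurable because public benchmarks include a visual
  latency offset.
- Default filterbank: four equal-width bands partitioning 8–30 Hz
  (8–13.5, 13.5–19, 19–24.5, 24.5–30).  An equal partition of the analysis
  range is the least arbitrary default; the bank is fully configurable.

## FBCSP numerics

- Covariances are per-trial trace-normalized (XXᵀ/tr XXᵀ), then averaged —
  the common convention; it equalizes trial power before averaging.
- Diagonal loading (1−γ)C + γ(tr C/Nch)I with γ = 1e-6 stabilizes the
  generalized eigenproblem; γ is raised automatically (with a warning) when
  cond(C₂) > 1e10.
- `scipy.linalg.eigh(C₁, C₂)` returns eigenvectors normalized to
  wᵀC₂w = 1, exactly the CSP constraint.  The kept 2p columns are the p
  largest- then p smallest-eigenvalue vectors.
- Sign ambiguity is fixed by making each column's largest-magnitude entry
  positive; ties in degenerate spectra are broken by a stable sort.  Models
  are therefore byte-reproducible.
- Variance uses the population (1/Nt) convention, consistent with the
  trace-normalized covariance; the natural logarithm is used (log base only
  rescales features).  Zero-variance projections are clamped at log(1e-12)
  and flagged.
- Feature ordering is class-major, then band, then filter column — declared
  and fixed so serialized models and features are interchangeable.

## DFN training

- Widths (500, 100, 50) with the constraints D₁ > I, D₂ < D₁, D₃ < D₂,
  D₃ > C enforced at build time; violations are configuration errors.
- He (fan-in) initialization; biases zero; batch norm starts in its identity
  state, so a zero input yields a uniform softmax at initialization.
- Batch norm: ε = 1e-5, running-statistic momentum 0.1, unbiased variance in
  the running estimate; inference uses running statistics.
- Adam with lr 0.001, β = (0.9, 0.999), batch 32, reshuffled each epoch with
  the seeded generator; the last incomplete minibatch is kept.
- Validation split: stratified 20% per class (seeded), guaranteeing every
  identity appears in both splits; an alternative `"one-block"` mode holds
  out one whole block when ≥ 3 training blocks exist.  200 epochs is a hard
  cap; the returned parameters are the snapshot with the lowest validation
  loss (ties → earliest epoch).
- Features are z-scored with training-fold statistics before *all three*
  classifiers — batch norm alone would not protect the distance-based
  baselines, and a shared scaling keeps the comparison about features.
- Ablations are expressed as the set of retained blocks ({B1,B2,B3},
  {B2,B3}, {B3}); the classification layer always remains.

## Baselines

k = 1 for kNN (the canonical template-matching choice) and C = 1.0 for the
one-vs-rest linear SVM; both configurable.  kNN ties are broken by smaller
mean neighbour distance, then lower class label — a declared deterministic
rule.

## Evaluation conventions

- Per-frequency CRR is computed on the confusion matrix pooled over the
  LOBO folds (identical to the mean of per-fold CRRs in this balanced
  design, but well-defined also for degenerate folds).
- U's training duration Tr defaults to 25 s — five training blocks of 5 s
  trials in a six-block design — and is explicitly configurable rather than
  derived, because different designs imply different training durations.
  CRR enters U on the percent scale.
- The one-way ANOVA utility uses the classical between/within decomposition
  (df = g−1, n−g), reporting F = +∞ when the within-group variance is zero
  with unequal means.  The "post hoc" comparison is implemented as pairwise
  Welch t-tests with Bonferroni correction — a deliberate, labelled
  interpretation, since post hoc procedures vary.

## Test problem sizes

The suite sizes its simulations for a single desktop CPU:

- Identity recovery and the chance-level null run at the full default
  conditions (10 subjects × 6 blocks, 5 s, 10 dB; 5 seeds).
- Trend checks run on a reduced design (6 subjects × 4 blocks).  The
  window-length sweep uses −10 dB SNR: at the default 10 dB every window
  length reaches 100% CRR and the trend is unmeasurable; −10 dB places the
  pipeline mid-range (≈ 47–89% CRR).  The ablation comparison uses 0 dB and
  0.5 s windows over 10 seeds, the regime where network capacity matters.

## Known limitations

- The generator's stationary-source assumption makes LOBO optimistic
  relative to recorded EEG, where inter-block drift is the main enemy.
- The NumPy DFN is single-threaded and CPU-oriented; it is exact but not
  fast for thousands of trials.
- Dataset loaders are adapters for the published on-disk layouts and are
  excluded from the tested surface; verify them against your local copy.
- Authentication-mode metrics (FAR/FRR/EER) are out of scope: the system
  performs closed-set identification only.
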