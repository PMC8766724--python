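# Methods

This note records the models, estimators and design choices behind
`thetanet`, and what the synthetic validation does and does not
demonstrate.

## The analysis problem

A working-memory (WM) task-EEG study of the kind this package supports
records multichannel scalp EEG during a delayed match-to-sample task,
together with an eyes-closed resting baseline and per-trial behavior
(correctness, reaction time). The analysis asks three questions:

1. **Oscillations.** Which frequency band dominates during the encoding
   phase, and how does its task-related power change (task minus rest)
   distribute over scalp regions?
2. **Networks.** Where does directed (Granger-causal) influence
   originate during encoding, summarized by the directed transfer
   function (DTF), and how do its global / node / region aggregates
   differ between groups?
3. **Behavior.** How is task performance linked to those EEG measures,
   and which patients are performance-impaired relative to control
   norms?

## Spectral model

Power spectral density is the average of squared short-time Fourier
transform magnitudes over 0.4-s Hamming windows with 50% overlap —
Welch's method with `density` scaling (µV²/Hz). Each windowed segment is
zero-padded to give a 0.5-Hz frequency grid. A 0.4-s window has a native
resolution of 2.5 Hz; the 0.5-Hz grid is therefore an interpolation of
that spectrum, not a sharpening — this is the only reading that
reconciles a 0.4-s window with a 0.5-Hz grid, and all band summaries are
averages over many grid bins, which the interpolation does not bias.
For epoched data, per-epoch spectra are averaged, producing one spectrum
per subject and channel; windows never cross epoch boundaries.

Band powers are **per-bin means** of the PSD over half-open bands
[low, high): delta [0.05, 4), theta [4, 8), alpha [8, 13), beta [13, 30),
gamma [30, 100) Hz. Half-open edges prevent double-counting at shared
endpoints; per-bin means (rather than band integrals) differ from
integrals only by a per-band constant, which cancels in every group
contrast. WM-efficiency power is the element-wise difference
`P_wm = P_raw − P_rs` (task-epoch minus resting-baseline band power) and
may be negative. The prominent band is the argmax of the channel-mean
band power, ties broken toward the lower band and logged.

The hot path computes the Welch average as one batched FFT in single
precision (relative error ~1e-7, negligible against estimation
variance); the test suite verifies agreement with `scipy.signal.welch`.

## Connectivity model

Encoding-phase EEG is modeled as a multivariate autoregressive (MVAR)
process of order p,

    x(t) = A_1 x(t−1) + … + A_p x(t−p) + e(t),

estimated by multi-epoch ordinary least squares: the regressor matrix
stacks lagged samples from all 60 encoding epochs of one subject, never
spanning an epoch boundary. One model per subject (not per trial): 4-s
epochs are short relative to the parameter count, and concatenation is
the variance-minimizing choice. Order selection is BIC by default over
1–8 (configurable, AIC available); the pattern-recovery benchmark fixes
p = 2, the generator's own order, to keep 50-replicate runs fast.

After common average referencing the regression is exactly rank-deficient
(one collinear direction per lag, since channels sum to zero); the
implementation uses the minimum-norm least-squares solution, the standard
resolution in MVAR toolboxes, and logs it. Deficiency beyond this
expected amount raises an error (insufficient data).

From the coefficients, the spectral transfer matrix is
`H(f) = [I − Σ_r A_r e^(−i2πfr/fs)]⁻¹` and the DTF from source channel j
to sink channel i is the row-normalized squared gain

    γ_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|².

Every row of γ sums to one at every frequency (tested at 1e-10). The
direction convention is `γ[sink, source]` everywhere, including exports.
Band-averaged γ (theta by default, 0.5-Hz grid) is aggregated as:

* `DTF_g` — mean off-diagonal entry (global coupling);
* `DTF_i` — per-channel `(Σ_{j≠i} γ_ji + γ_ij) / (2(n−1))` (in+out
  strength); region strength is the unweighted mean of `DTF_i` over a
  region's channels;
* `DTF_kl` — mean of γ over sink-region rows and source-region columns;
  within-region values exclude the diagonal (γ_ii is a normalization
  remainder, not a connection; single-channel regions have no
  within-region value);
* `DTF_out` / `DTF_in` — means of `DTF_kl` over non-hub sinks (sources
  fixed to the hub region) and non-hub sources respectively, hub = F by
  default.

## Montage and regions

The 34-channel extended 10-20 montage is grouped as F (Fp1, Fp2, F3, Fz,
F4, FC3, FCz, FC4, AF3, AF4), C (C3, Cz, C4, CP3, CPz, CP4, P3, Pz, P4),
O (PO3, PO4, O1, Oz, O2) and T (FT7, FT8, T7, T8, TP7, TP8, P7, P8).
Legacy temporal names map by the standard nomenclature equivalence
(T3→T7, T4→T8, T5→P7, T6→P8). F7 and F8 belong to no cluster; they stay
in whole-scalp computations but never enter region aggregates. A reduced
16-channel sub-montage covering all four regions exists for fast
simulation profiles.

## Preprocessing

Low-pass 100 Hz, notch 49–51 Hz, common average reference, baseline-drift
removal (per-channel linear detrend by default; zero-phase high-pass at
0.05 Hz optional). All filters are 4th-order Butterworth applied
forward–backward (zero-phase), so epoch timing is never shifted; the
family is a choice — standard EEG practice with a testable frequency
response. Filters whose band sits above Nyquist at a reduced sampling
rate are skipped with a log message. Sample indexing is 0-based and
half-open: an event at onset o with duration d covers samples
[o, o+d). Artifact removal is a no-op hook: synthetic cohorts carry no
ocular/myogenic artifacts, and real-data users can inject their own
callable.

## Behavioral phenotyping and statistics

Per subject: accuracy = correct/total, RT = mean over **correct trials
only** (undefined, and flagged, when no trial is correct). Patients are
z-scored against the control group's mean and sample SD (n−1) and
classified impaired when `z_RT > 1.5` or `z_ACC < −1.5`. The rule is
directional — unusually fast or accurate performance is not a deficit —
with a two-sided variant behind a flag. Controls are scored but keep
their control status. The threshold (1.5 SD) is the conventional
normative cutoff and is configurable.

The battery: Student t (Welch optional), one-way ANOVA with Fisher's LSD
post-hocs (pairwise t on the pooled within-group mean square with its
N−k df, no multiplicity correction — that is the definition of LSD),
Pearson chi-square without continuity correction, Pearson correlation
(two-sided p via the t transform), and Shapiro-Wilk/Levene assumption
checks reported alongside every parametric test. Assumption failures are
logged, never acted on automatically. No multiple-testing correction is
applied anywhere.

In the pipeline, statistics compare `Con` against patients split by the
phenotyping rule itself into `patient-normal` and `patient-impaired`
analysis groups; generator ground-truth flags are reserved for recovery
scoring.

## The synthetic cohort generator

No patient EEG is distributed with studies of this kind, so every stage
is validated against a generator whose ground truth is known exactly.
Each subject's EEG is a stable MVAR(2) process:

* **Theta resonance.** Every channel has an oscillatory AR(2) pole pair
  at 6 ± 0.5 Hz with radius 0.96. At 256 Hz sampling this radius is what
  makes theta an actual spectral peak: broader poles leave the resonance
  skirt covering the delta band. Shaping the spectrum with poles only
  (never with moving-average zeros) keeps the process exactly
  representable by the MVAR estimator — an earlier design that
  high-passed the innovations with a unit-circle zero made every fit
  misspecified and biased the inflow estimates.
* **Background network.** Weak random pairwise lag-1 couplings (SD
  0.03, per-subject lognormal scale jitter of 0.6) shared between rest and task.
  This is the group-independent anatomical backbone; it gives DTF_in a
  genuine, variable floor, as in real cohorts, rather than leaving
  inflow estimates at the mercy of estimation bias.
* **Frontal hub.** During task segments only, Fz drives all other
  frontal and all occipital channels with lag-1 coefficients
  (`coupling_gain`, default 0.01, per-subject lognormal jitter).
  The gain is deliberately placed in the DTF-sensitive regime: with a
  sharp resonance, much larger couplings saturate γ near 1 across the
  band and group differences vanish. In the impaired group the hub
  coefficients are multiplied by `impairment_factor` (default 0.5).
  Because the hub block and background are checked jointly, a stability
  margin (companion spectral radius < 0.985) is enforced by shrinking
  the background only — never the hub outflow, which is the effect under
  study.
* **Latent behavior link.** A per-subject standard-normal scalar scales
  the frontal innovation gain during task segments (so frontal theta
  P_wm varies across subjects) and shifts behavior: trial RT mean
  decreases and accuracy (logistic link) increases with the latent. The
  impaired group receives a −1 SD latent shift, a +3 trial-SD RT shift
  and a logit-scale accuracy deficit, so the 1.5-SD rule flags them with
  high probability. RT is drawn per correct trial only.

Defaults are a desk-scale profile: fs = 256 Hz, 60-s baseline, 60
encoding epochs of 4.039 s, 34 channels (16-channel reduced montage in
the Monte-Carlo benchmarks). The clinical acquisition this emulates ran
at 1,024 Hz with a 5-minute baseline; both are reachable through the
config. Determinism: one root seed; subjects, behavior and experiment
replicates draw from named `SeedSequence` substreams.

### What the generator does not emulate

No ocular or myogenic artifacts, no volume conduction or source mixing,
no 1/f broadband background, no nonstationarity within epochs, no
trial-locked neural-behavioral coupling (the link is a subject-level
latent), and no seizure-related activity. Passing recovery tests
therefore shows the estimators are correct and well-calibrated for the
assumed process class — not that the pipeline is robust to artifacts or
conduction effects in clinical recordings.

## Validation experiments and problem sizes

* **Analytic oracles** (seconds): closed-form 2×2 transfer-matrix
  inversion; brute-force aggregation loops; row-normalization identity.
* **Null calibration** (~1 min): 10 independent AR(2) channels, 50,000
  samples — median off-diagonal band DTF stays below 0.05; behavior-only
  null cohorts (no link, no shifts), 200 replicates — the one-sided
  1.5-SD rule flags ≈13% of patients (two one-sided 6.7% tails, minus
  the overlap induced by the RT-ACC correlation, plus control-norm
  estimation noise).
* **Pattern recovery** (~10–13 min, the dominant cost): 50 replicates of
  a 20-per-group cohort at the smoke profile; per replicate the full
  path (simulate → CAR + detrend → epochs → band power → MVAR(2) → DTF →
  phenotype → ANOVAs) must find theta prominent, significantly lower
  DTF_g, frontal strength and DTF_out in the impaired group, and no
  significant DTF_in difference. The low-pass and notch filters are
  skipped in this benchmark (band-limited noise-free synthetic data at
  256 Hz; both filters are near-identity there) — they are exercised by
  their own tests.
* **Correlation sign** (~3 min): 50 replicates, 35 controls each;
  frontal theta P_wm vs mean RT correlation must be negative.
* **Label recovery** (~1 min): 100 behavior-only replicates; phenotype
  labels vs ground-truth flags, scored over all subjects with controls
  retaining control status — ≥95% accuracy at the default 3-SD shift.

## Known limitations

* DTF is estimated, not thresholded: no surrogate-data edge
  significance, no partial directed coherence, no time-varying models.
* γ estimates of near-zero couplings are positively biased at finite
  samples (ratio-of-quadratics estimator); group comparisons inherit a
  small SNR-dependent component of that bias. The generator's
  between-subject variability keeps it well below effect sizes of
  interest, but exact nulls on DTF differences are approximate.
* Sensor-space DTF on common-average-referenced data mixes sources; the
  reference also injects a small common-mode coupling. Both affect real
  studies of this design equally; conclusions should be read as
  sensor-level, not source-level.
* EDF export quantizes to 16 bits per channel-specific physical range;
  the delimited format is the lossless interchange.
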