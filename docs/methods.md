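# Methods

This note documents the models, estimators and design choices behind
`emgpac`, and what the synthetic cohort does and does not establish.

## The diagnostic question and the pipeline's shape

The pipeline asks whether cross-frequency structure in surface EMG — a
slow rhythm's phase modulating a fast component's amplitude (PAC) —
separates patients from controls where per-epoch amplitude and spectral
summaries do not. Everything downstream (feature tables, separability,
classifier, evaluation statistics) is organised around one analysis
unit: a (channel, 500 ms epoch) row tagged with its subject and group.
Subject-level diagnosis aggregates row-level classifier probabilities by
their mean against a 0.5 cutoff; validation is leave-one-subject-out
(LOSO), which is the weakest protocol under which a row-level classifier
can legitimately claim subject-level generalisation.

## Synthetic cohort

The study data the pipeline was designed around are not public, so the
simulator is a first-class, tested component that reproduces the
*statistical structure* the method assumes, with known ground truth.

Background activity per channel is Gaussian noise band-limited to
20–450 Hz (4th-order zero-phase Butterworth) and scaled to a target RMS
(1.0 arbitrary units). Defaults mirror the recording conditions the
pipeline targets: 2048 Hz sampling, four muscles (ECR, EDC, ECU, FCR) ×
7 single-differential channels, per-subject exercise durations drawn
uniformly from 9.1–95.9 s, 14 cases + 14 controls, and a bad-channel
rate of 0.12 (≈3.3 of 28 channels, matching the reported removals).

**Coupling model.** On the coupled muscles (default ECR, EDC), case
channels receive

    a(t) = m · rms · [ (1 + cos(2π f_p t + φ))/2 · cos(2π f_a t + ψ)
                       + 0.3 · cos(2π f_p t + φ) ]

with per-subject jitter (relative s.d. 0.05) on f_p = 10 Hz,
f_a = 150 Hz and m (default 0.8), and per-channel random phases. Two
points deserve emphasis:

* *The slow rhythm must be present.* A pure AM signal
  (1+cos 2πf_p t)·cos 2πf_a t has **no** spectral energy at f_p, so the
  phase extracted at f_p is numerically meaningless and no
  phase-referenced estimator can recover the coupling (we measured
  coherence ≈ 2×10⁻⁴ on that signal and chance-level comodulogram
  recovery). Physiological PAC consists of a slow rhythm *and* a fast
  component locked to it; the generator therefore injects the rhythm
  term, phase-locked to the envelope. Its gain (0.3) was set from two
  constraints: >95 % of channel power must stay in the 20–450 Hz band
  (the rhythm sits below the band edge), and full-grid comodulogram
  recovery must succeed at m = 0.5 (both hold; at gain 0.5 the spectral
  constraint fails).
* *Controls are matched, not empty.* Control channels on the same
  muscles receive the same-depth AM carrier modulated at a fast,
  unrelated rate (50 Hz) plus a slow rhythm with independent phase.
  Case and control channels then share amplitude statistics, RMS (all
  channels are rescaled to the target RMS after injection), and spectral
  summaries (the AM sidebands are symmetric, so mean frequency is
  unchanged); only the phase-amplitude *locking* differs. This is what
  makes the benchmark honest: classic features stay near chance not
  because controls are trivially quiet but because every marginal
  statistic is matched, mirroring the claim that the coupling itself is
  the discriminative signal. A spec-literal mode with background-only
  controls is available (`control_mode="noise"`), under which classic
  features become strongly informative through the injected component's
  line spectrum.

Per-subject random streams derive from `SeedSequence((seed, subject_index))`,
so any subject regenerates in isolation and identical configurations are
bit-identical.

**What the simulator does not emulate:** motor-unit action-potential
trains, force/fatigue dynamics, electrode geometry, nonstationarity
within an exercise, or real EMG's heavy-tailed amplitude structure.
Passing the end-to-end tests shows the *pipeline* is correct and
sensitive to PAC under realistic SNR; it does not show that real
patients exhibit this coupling.

## PAC estimation

Phase and amplitude come from convolution with unit-L2-energy complex
Morlet wavelets. The width parameter 7 is interpreted as *cycles*
(σ_t = 7/(2πf)); a literal 7-second Gaussian width at every frequency
would be physically meaningless at 2048 Hz. Support is truncated at
±4σ_t; frequencies whose support exceeds the analysis window are dropped
with a warning.

Coupling is the magnitude-squared coherence between
ph(t) = cos ∠W(f_p, t) and amp(t) = |W(f_a, t)| — the cosine makes the
coherence a well-defined quantity between two real series — estimated by
Welch (256-sample Hann segments, 50 % overlap, constant detrend) and
read at the Welch bin nearest f_p, never the DC bin. Coherence needs ≥2
segments; on a single segment it is identically 1.

A 500 ms epoch cannot resolve low phase frequencies (the 2 Hz wavelet
alone spans 4.5 s) nor give stable Welch averaging, so per-epoch PAC
features are computed on 4 s analysis windows (8 consecutive epochs per
channel) and shared by the epochs inside a window; trailing epochs fall
back to per-epoch estimation with 128-sample segments, and cells whose
phase wavelet cannot fit an epoch are reported as 0 (no coupling
evidence). This windowing is the largest interpretive gap in the
estimator's provenance and is therefore explicit and configurable.

The default comodulogram grid is phase 2–30 Hz (step 2) × amplitude
30–350 Hz (step 10), with cells where f_amp ≤ f_phase masked;
`paper_mode_grids` exposes the full 1–350 Hz span on both axes. The
flattened vector names cells `PAC_<fp>_<fa>` and is invertible back to
the matrix.

Measured properties (asserted in tests): comodulogram values lie in
[0, 1]; the estimate is exactly invariant to amplitude scaling; the
argmax falls within one grid cell of the injected (f_p, f_a) in ≥90 % of
seeded runs at m ≥ 0.5; and mean coherence at the true cell is strictly
increasing in m (Spearman ρ = 1 on Monte-Carlo means).

## Classic and wavelet features

The sixteen classic features follow the standard definitions, with three
conventions made explicit because the usual formulae leave them open:
v-order and the log detector operate on |x| (fractional powers and logs
of negatives are undefined), the log detector defaults to the
geometric-mean form exp(mean ln|x|) with the literal base-10-under-e
variant kept as an option, and TM3/TM5 are reported as absolute values.
MYOP/ZC/SSC/WAMP share one amplitude threshold (0.01, raw units); the ZC
condition is the standard conjunction of a sign change and a
threshold-clearing step. Spectral features use the full-epoch one-sided
periodogram with DC excluded; the median frequency is the first bin
whose cumulative power reaches half the total.

Wavelet features use the level-4 db4 DWT with periodized boundary, so
Parseval holds exactly and reconstruction is checked to 1e-10. Which
scalar summarises a subband is not canonical; the default is RMS and MAV
per subband (10 features, fixed order), configurable and used
consistently across the separability and classifier comparisons.

## Separability and its aggregation

Eq.-level JM is univariate; a feature set is summarised by the *mean*
per-feature JM on the training rows of each LOSO dataset (max and median
are also emitted — the reduction is a reporting choice, not implied by
the distance). Zero-variance features abort with the offending feature
named; the pipeline drops such features with a warning before the
report.

On the synthetic cohort the PAC set's JM exceeds both other sets by two
orders of magnitude (≈0.22 vs ≈0.002 at desk scale). The wavelet set
does carry a structural signal the classic set lacks (the controls' AM
sidebands straddle dyadic band edges), but at desk-scale cohort sizes
both non-PAC JMs sit at the sampling-noise floor and their mutual
ordering is not stable across seeds; tests therefore assert the robust
ordering (PAC above both) only.

## Classifier and LOSO protocol

The feedforward net (4 hidden layers × 128 ReLU units, dropout 0.2
after each hidden layer, sigmoid output, binary cross-entropy, Adam at
1e-3, batch 32, exactly 20 epochs, He-uniform initialisation) is
implemented directly on NumPy: this pins the architecture — including
dropout — precisely, keeps training bit-reproducible from a seed in
single-threaded runs, and trains in float32 for speed. No early
stopping or checkpoint selection is performed.

One dataset is built per subject: the held-out subject's rows form the
test set; the remaining rows are split 80/20 into train/validation at
the *row* level (the protocol being reproduced splits rows, not
subjects); per-feature z-scalers are fitted on training rows only and
applied to validation and test. Leakage is asserted per dataset, not
assumed. An exact 0.5 mean probability resolves to "case" (favouring
sensitivity) and is flagged.

The random-label control permutes *subject-level* group labels before
the full LOSO sweep; because coupling structure no longer aligns with
labels, subject accuracy collapses (0.32 on the scaled-down cohort).

## Evaluation statistics

Wald binomial intervals (clipped to [0, 100] %) are the default because
they reproduce the bracketed intervals of the reporting convention this
package follows; Clopper–Pearson is available. McNemar defaults to the
exact binomial form (28 subjects is small) with Cohen's
g = |b/(b+c) − ½|. Wilcoxon post hocs are one-sided with exact p for
n ≤ 30 without ties and rank-biserial (W⁺−W⁻)/(W⁺+W⁻) as the effect
size; Bonferroni uses family size 3 for both the JM and classifier
comparison families. The Bayesian interval treats thresholded epoch
predictions as Bernoulli draws with a uniform Beta prior (configurable)
and reports equal-tailed posterior quantiles. The AUC sample-size
routine iterates n upward under the Hanley–McNeil variance
(Q1 = A/(2−A), Q2 = 2A²/(1+A)); it reproduces the design value n = 13
per group for AUC 0.95 vs 0.7 at one-sided α = 0.05 and 95 % power.

## Problem sizes and numerical choices

The end-to-end acceptance study uses a scaled-down cohort the package
defines once (`scaled_down_config`): 14+14 subjects, 20 s per subject,
3 channels per muscle, PAC grid {6, 10, 14} × {70, 110, 150, 190, 230} Hz
— chosen so a full three-arm LOSO sweep (PAC, classic, random-label; 84
network fits) completes in minutes on one CPU while preserving cohort
composition and coupling parameters. Unit tests use smaller cohorts
still. Tolerances: transform identities at 1e-10, closed-form statistics
at 1e-9 relative, measured signal properties at the few-percent level
stated with each test. Degenerate inputs (all-zero spectra, single-class
tables, zero discordance, fully tied Friedman blocks, zero-variance
features) raise or flag explicitly rather than propagating NaN.

## Known limitations

* The PAC estimator's exact windowing in its original setting is not
  recoverable; both implemented modes are documented choices.
* The wavelet feature set's dimensionality in the original setting is
  unknown; subband RMS/MAV is this package's explicit choice.
* EDF output is quantised to 16 bits (standard EDF); only the CSV path
  round-trips bit-exactly. EDF reading requires `mne`.
* The simulator's sinusoidal carrier gives clean ground truth; the
  band-limited-noise carrier option is more realistic but has no exact
  (f_p, f_a) line structure.
* Desk-scale runs cannot resolve the wavelet-vs-classic separability
  ordering; only the PAC set's dominance is a stable effect.
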