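# emgpac

Phase–amplitude-coupling (PAC) diagnostics for high-density surface EMG
(HD-sEMG), built around the question: *can cross-frequency structure in
forearm-muscle EMG separate patients with lateral epicondylitis ("tennis
elbow") from healthy controls where conventional EMG features cannot?*

The package is aimed at biomedical-signal researchers who want a tested,
reproducible implementation of the full diagnostic pipeline:

1. **Synthetic cohort simulator** — two-group HD-sEMG recordings
   (2048 Hz, four forearm muscles × 7 single-differential channels,
   exercise durations 9.1–95.9 s) in which cases carry injected PAC: a
   slow rhythm at `f_p` (default 10 Hz) whose phase modulates the
   amplitude of a fast carrier at `f_a` (default 150 Hz). Controls are
   amplitude- and spectrum-matched, so the class signal lives only in the
   phase–amplitude locking.
2. **Preprocessing** — 20–450 Hz second-order Butterworth band-pass
   (zero-phase by default), bad-channel removal, segmentation into 500 ms
   epochs; the analysis unit is one (channel, epoch) row.
3. **Feature families** —
   * *classic*: RMS, v-order, log detector, MAV, MYOP, ZC, SSC, WAMP,
     temporal moments TM3–TM5, waveform length, DASDV, square integral,
     mean/median frequency;
   * *wavelet*: level-4 db4 decomposition, RMS/MAV of each subband
     (A4, D4, D3, D2, D1);
   * *PAC*: complex Morlet transform (σ = 7 cycles, unit-energy wavelets)
     gives instantaneous phase `ph(t) = cos ∠W(f_p, t)` and envelope
     `amp(t) = |W(f_a, t)|`; coupling is the magnitude-squared coherence

     C(f_p, f_a) = |P_ph,amp(f_p)|² / (P_ph,ph(f_p) · P_amp,amp(f_p)),

     Welch-estimated and scanned over a (phase × amplitude) grid to give
     a comodulogram, flattened into the PAC feature vector.
4. **Separability** — per-feature Bhattacharyya distance
   D_B = ¼ln[¼(σ_p²/σ_q² + σ_q²/σ_p² + 2)] + ¼(μ_p−μ_q)²/(σ_p²+σ_q²)
   and Jeffries–Matusita distance JM = 2(1 − e^(−D_B)) ∈ [0, 2).
5. **Classifier** — feedforward net (4 × 128 ReLU, dropout 0.2, sigmoid,
   binary cross-entropy, Adam 1e-3, batch 32, 20 epochs) under
   leave-one-subject-out (LOSO) validation; a subject is diagnosed as a
   case when the *mean* epoch probability ≥ 0.5.
6. **Evaluation statistics** — Se/Sp/Acc with Wald (or Clopper–Pearson)
   intervals, diagnostic odds ratio DOR = Se·Sp/((1−Se)(1−Sp)),
   prevalence-adjusted PPV, McNemar + Cohen's g, Friedman and one-sided
   Wilcoxon post hocs with rank-biserial effect sizes and Bonferroni
   correction, 99.9 % mean-probability CIs, Beta-posterior credible
   intervals, and Hanley–McNeil AUC-based sample-size computation.

## Worked example

```python
import pandas as pd
from emgpac import FNNSpec, LOSOClassifier
from emgpac.simulate import scaled_down_config, generate_cohort
from emgpac.preprocess import preprocess
from emgpac.features.pac import pac_feature_table

recordings, manifest = generate_cohort(scaled_down_config(seed=0))
table = pd.concat(
    [pac_feature_table(preprocess(rec),
                       phase_freqs=[6.0, 10.0, 14.0],
                       amp_freqs=[70.0, 110.0, 150.0, 190.0, 230.0])
     for rec in recordings], ignore_index=True)

results = LOSOClassifier(table, spec=FNNSpec()).fit(seed=0)
print(results.summary())
```

This trains 28 nets (one per held-out subject) on the scaled-down cohort
(14 cases + 14 controls, 20 s each, 3 channels per muscle) and prints:

```
Leave-one-subject-out diagnosis summary
===============================================
subjects: 28   feature columns: 15
confusion: TP=14 FN=0 TN=14 FP=0
sensitivity: 100.00%  CI [100.00, 100.00]
specificity: 100.00%  CI [100.00, 100.00]
accuracy:    100.00%  CI [100.00, 100.00]
-----------------------------------------------
     p00      case -> case     mean_prob=0.651
     ...
     s27   control -> control  mean_prob=0.280
```

Every case subject's mean epoch probability lands near 0.63–0.70 and
every control near 0.26–0.35, so the 0.5 cutoff separates the cohort
perfectly — while the same pipeline run on the sixteen classic features
of the *same* recordings stays near chance (the simulator matches RMS
and spectral summaries across groups on purpose). The CLI exposes the
same chain: `emgpac all --quick --seed 0 --out run/`.

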