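# eegvuln

Resting-state and task-based EEG analysis for predicting **vulnerability to
depression**, packaged as a tested, reusable pipeline.

The scientific setting: two groups of non-clinical participants — scoring
high vs low on summed standardized rumination and depression questionnaires
(PTQ, RRS, CES-D) — are recorded at rest (5 min eyes closed, 32-channel
10–20 cap, 512 Hz) and during a sustained attention to response task (SART,
8 blocks × 90 trials) with thought probes rating the *stickiness* of
ongoing thought (1–9).  The analysis asks which channels and which
biomarkers separate the groups, and how well classifiers can tell them
apart.

Because raw recordings are not distributable, `eegvuln` ships a first-class
**synthetic cohort generator** with planted, recoverable group effects, so
every stage of the analysis is verifiable end to end:

1. **synth** — 1/f-background EEG for n = 20 + 20 subjects with
   band-limited amplitude effects at named channels and phase-lagged
   coupling effects at named pairs; SART event sequences; questionnaire
   tables with the study's group means/SDs and missingness.
2. **preprocess** — zero-phase 0.5–40 Hz band-pass, epoching
   (−500..+1300 ms), baseline correction, peak-to-peak artifact rejection,
   neighbour interpolation, average re-reference, crop to −200..+1300 ms.
3. **features** — band powers (and log-power), relative gamma, frontal
   alpha asymmetry ln P_α(F4) − ln P_α(F3), correlation, coherence
   |Coh| and Im(Coh), phase-locking value (PLV), phase-lag index (PLI),
   Higuchi fractal dimension (HFD), DFA exponent.
4. **groupstats** — independent t-tests (pooled or Welch, also from printed
   summaries), 2×2 chi-square, Benjamini–Hochberg FDR at q = 0.05,
   channel-wise tests with topographic masking (non-significant channels
   plotted as t = 0).
5. **featselect** — binary wrapper selection of biomarker subsets with
   grey-wolf optimization, a genetic algorithm and particle-swarm
   optimization over decision-tree fitness.
6. **classify** — DT, MLP, 1-D CNN, LSTM and BLSTM on 32-sample windows,
   60:20:20 or k = 5 cross-validation, sample-level *and* subject-level
   splits (the latter immune to within-subject leakage), with
   accuracy/confusion/precision/recall/F1 reports.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from eegvuln import synth, preprocess
from eegvuln.features import extract_feature_table
from eegvuln.groupstats import channelwise_group_test, ttest_from_summary, chi2_2x2

# Printed questionnaire summaries reproduce the group statistics:
r = ttest_from_summary(45.85, 4.70, 20, 25.10, 8.33, 20)   # PTQ high vs low
print(f"PTQ: t({r.df:.0f}) = {r.t:.2f}, p = {r.p:.2e}")
print(f"gender: chi2 = {chi2_2x2([[16, 4], [9, 11]]).chi2:.2f}")

# A cohort with a planted x1.5 delta-amplitude effect at O2:
spec = synth.CohortSpec(
    n_high=20, n_low=20, rest_duration_s=30.0, seed=7,
    effect=synth.EffectSpec(
        amplitude_effects=(synth.AmplitudeEffect("O2", "delta", 1.5),)),
)
recs, quest = synth.generate_cohort(spec)
eps = [preprocess.rest_to_epochs(r, 2.0) for r in recs]
ft = extract_feature_table(eps, ["log_power"], ["delta"])
gsr = channelwise_group_test(ft, q=0.05)
print("FDR-significant channels:", gsr.significant,
      f"(p threshold {gsr.fdr.p_threshold:.2e})")
```

prints

```
PTQ: t(38) = 9.70, p = 7.86e-12
gender: chi2 = 5.23
FDR-significant channels: ['log_power|delta|O2'] (p threshold 3.80e-05)
```

— the t statistic and chi-square match the questionnaire table they were
computed from, and the only channel surviving FDR correction is exactly the
one where the effect was planted.

## Command line

```bash
eegvuln run --seed 1 --out-dir demo_run          # full pipeline + report
eegvuln simulate --out-dir sim --save-recordings # cohort to containers
eegvuln stats features.tsv --out topo.tsv        # channel-wise FDR test
eegvuln select features.tsv --algorithm gwo --out sel.txt
eegvuln report demo_run
```

Every run writes a `manifest.json` with config echo, stage timings and
SHA-256 checksums; identical configs give bit-identical outputs.

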