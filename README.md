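# screamkit

Spectro-temporal analysis of primate agonistic screams: scream/bout/event
segmentation, call- and bout-level acoustic features with non-linear-phenomena
(NLP) detection, permuted jack-knifed discriminant function analysis (pDFA),
and mixed-effects inference with false-discovery-rate control.

## Who this is for

Bioacousticians and behavioural ecologists analysing agonistic vocalisations
recorded in the field: screams annotated with the caller's identity, social
role (aggressor vs victim), conflict severity (mild vs severe), recording
context and third-party support.  The package covers the full desk workflow —
from WAV files and annotation tables to the statistical result tables — and
includes a synthetic scream generator with known ground truth so every stage
is testable without field recordings.

## The analysis in brief

**Units.** A *scream* is a voiced utterance whose internal silent gaps are at
most 0.03 s; screams separated by at least 0.3 s of silence are distinct.  A
*bout* is a conflict stage with constant caller, social role and conflict
severity.  An *event* is an agonistic interaction; 30 s without agonism or a
change of the interacting partners starts a new event.

**Features (15).** Per scream: duration; peak frequency; coefficients of
frequency variation (sd/mean) and modulation (mean|Δf|/mean) of the
dominant-frequency contour; signed frequency transitions at onset and offset;
the 50% energy quartile Q50; the inter-quartile range Q75 − Q25; and the
normalized Shannon spectral entropy

&nbsp;&nbsp;&nbsp;&nbsp;H = −Σᵢ pᵢ log pᵢ / log N,&nbsp;&nbsp;pᵢ = mean power in bin i (white noise → 1, pure tone → 0),

computed from 512-sample Hann spectrograms at 90% overlap (44.1 kHz).  Per
bout: bout duration, number of screams, average scream duration, mean
inter-scream interval, scream rate, and the percentage of screams with at
least one NLP form (frequency jump, sub-harmonics, bi-phonation,
deterministic chaos), flagged by rule-based detectors on an f0-aligned order
spectrum.

**pDFA.** Features are de-correlated (|r| > 0.8), symmetry-transformed and
standardized; Fisher discriminants are fitted on balanced training subsets
(crossed over role × severity) and applied to held-out calls.  Observed
classification and cross-validation rates are calibrated against the same
procedure on datasets whose test-factor labels are permuted within control
cells, giving empirical expected rates and p-values
p = (#{perm ≥ observed} + 1)/(n_perm + 1).

**Mixed models.** Each of 12 retained parameters is modelled as
`feature ~ role * severity + (1|caller) + (1|event)` by REML; third-party
support as a binomial-logit GLMM with caller and context intercepts (Laplace
approximation).  The 36 fixed-effect p-values are adjusted jointly by
Benjamini–Hochberg; marginal/conditional R² follow the variance-partition
formulation.  Cohen's kappa quantifies inter-observer reliability.

## Worked example

```python
from screamkit import (StudyConfig, simulate_study, extract_all,
                       DFADesign, run_pdfa, run_all_models)
from screamkit.features import CALL_FEATURES

study = simulate_study(StudyConfig(seed=11))          # 374 screams, 119 bouts,
call, bout = extract_all(study.clips, study.annotations)  # 95 events, 26 callers

design = DFADesign(test_factor="caller_id", control_factor=["role", "severity"],
                   mode="balanced_crossed", n_resamples=100,
                   n_permutations=1000, seed=42)
res = run_pdfa(call, CALL_FEATURES, design)
print(f"cross-validated: observed {res.observed_crossvalidation:.1f}% "
      f"vs expected {res.expected_crossvalidation:.1f}%, "
      f"p = {res.p_crossvalidation:.4f}")

ledger = run_all_models(call, bout)
sig = ledger[ledger.significant]
print(sig[["response", "effect", "estimate", "p_adjusted"]].to_string(index=False))
```

Output (seed 11; post-BH significant rows):

```
cross-validated: observed 29.2% vs expected 16.7%, p = 0.0020
           response                        effect  estimate   p_adjusted
           duration                  role[victim]  1.356714 5.524474e-36
          peak_freq                  role[victim]  0.700530 8.430539e-09
           coef_mod              severity[severe]  0.376843 4.070574e-02
                q50                  role[victim]  0.724462 5.270386e-10
                q50              severity[severe]  0.495596 2.203205e-04
                q50 role[victim]:severity[severe] -0.407986 2.887496e-02
                iqr                  role[victim]  0.727381 4.729514e-09
                iqr              severity[severe]  0.541274 1.574388e-04
                iqr role[victim]:severity[severe] -0.684937 2.203205e-04
            entropy                  role[victim]  0.293227 4.272326e-02
            entropy              severity[severe]  1.215328 3.101517e-17
avg_scream_duration                  role[victim]  1.635078 4.967070e-35
        scream_rate                  role[victim] -0.684671 2.666590e-03
        scream_rate              severity[severe] -0.834070 1.071298e-03
            pct_nlp              severity[severe]  1.338730 2.951386e-08
```

Read: caller identity is recoverable from single screams well above the
permutation-expected rate (29.2% vs 16.7% cross-validated over the callers
eligible for the balanced design).  Victims scream longer and at higher
frequencies (peak, Q50, IQR all shift with the configured +200 Hz victim
signature); severe conflicts produce noisier screams (higher entropy, more
non-linear phenomena) delivered at lower rates.  Estimates are on the
transformed, standardized response scale.

A command-line interface mirrors the stages:

```bash
screamkit simulate --out run/ --seed 11
screamkit extract  --wav-dir run/ --annotations run/annotations.csv --out run/feat
screamkit pdfa     --features run/feat/call_features.csv --test caller_id \
                   --control role,severity --mode balanced_crossed --seed 42 --out run/dfa.json
screamkit models   --call run/feat/call_features.csv --bout run/feat/bout_features.csv \
                   --out run/models.json
screamkit report   --effects run/models.json --out run/report.md
```

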