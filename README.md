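# tva-arousal

Tools for studying **hypoarousal**: the link between visual processing
speed, central nervous activation and mental fatigue — as observed, for
example, in post-COVID patients with subjective cognitive dysfunction.

The package implements, as one tested pipeline:

1. **TVA-based attention parameter estimation.**  In the theory of visual
   attention (TVA), briefly exposed letters race in parallel for encoding
   into a capacity-limited visual short-term memory (vSTM) store.  For a
   whole-report display of six equally weighted letters at effective
   exposure *a* = max(0, τ + μ·[unmasked] − t₀), each letter is encoded with
   probability *p* = 1 − exp(−(C/6)·a), and the report score is
   min(Binomial(6, p), K) with capacity K drawn from a two-point mixture on
   adjacent integers.  Maximum-likelihood fitting across seven exposure
   conditions yields visual processing speed *C* (letters/s, a proxy of
   tonic alertness), perceptual threshold *t₀* (ms), vSTM capacity *K* and
   iconic persistence *μ* (ms).  Partial report with target and distractor
   letters (rates v = C·w/Σw) adds the top-down selectivity ratio
   *α* = w_D/w_T.
2. **Pupillary unrest.**  The pupillary unrest index (PUI, mm/min)
   quantifies slow "fatigue wave" oscillations of the dark-adapted pupil:
   an 11-minute 25-Hz recording is artifact-cleaned, block-averaged over 16
   samples (1.5625 Hz), and the absolute differences of consecutive block
   means are summed per 82.5-s segment (127 differences), normalised per
   minute, and averaged over the eight segments.  A stable pupil gives 0;
   drowsiness gives high values along with a smaller mean diameter (PD).
3. **Synthetic cohorts.**  A Gaussian-copula generator draws subject-level
   tables (C, K, t₀, α, PUI, PD, fatigue, depression, sleepiness, age, time
   from infection) with configurable group means/SDs and target Spearman
   correlations, plus trial-level report data and raw pupil traces, so the
   entire pipeline is testable without patient data.
4. **The statistics battery.**  One-/two-tailed Wilcoxon rank-sum tests
   with effect size r = |z|/√N, bootstrapped kernel-density non-overlap,
   Spearman correlation matrices with Benjamini–Hochberg FDR, multiple
   regression with case-resampling bootstrap CIs and Cohen's
   f² = R²adj/(1 − R²adj), nested-model F-tests, and percentile-bootstrap
   mediation (indirect = a·b).

## Worked example

Simulate a subject at typical healthy-control parameters, refit, and score
a pupil recording:

```python
from tva_arousal import (
    TVAParameters, FitConfig, simulate_whole_report, fit_whole_report,
    simulate_pupil_trace, preprocess_trace, compute_pui,
)

truth = TVAParameters.from_continuous(C=33.77, t0=5.96, K=3.85, mu=150.0)
trials = simulate_whole_report(truth, seed=2)          # 7 conditions x 20 trials
fit = fit_whole_report(trials, FitConfig(seed=2))
print(f"C={fit.params.C:.2f} t0={fit.params.t0:.2f} "
      f"K={fit.params.K:.2f} R2={fit.R2_fit:.3f}")

trace = simulate_pupil_trace(base_pd_mm=6.3, oscillation_amplitude_mm=0.35,
                             oscillation_freq_hz=0.12, seed=3)
res = compute_pui(preprocess_trace(trace))
print(f"PUI={res.total_pui:.2f} mm/min, PD={res.mean_pd:.2f} mm")
```

Output:

```
C=31.86 t0=3.35 K=3.88 R2=0.994
PUI=9.75 mm/min, PD=6.15 mm
```

The fitted curve explains 99% of the variance in mean report scores across
the seven exposure conditions; the drowsy-profile pupil trace (high
oscillation amplitude, small diameter) yields a high unrest index.

The full analysis chain lives in `analysis/` as numbered drivers:
`01_simulate_cohort.py` (synthetic 40 + 40 cohort), `02_fit_attention_parameters.py`
(ML fits at the group medians), `03_pupillary_unrest.py` (alert vs drowsy
PUI), `04_group_comparisons.py` (rank tests, effect sizes, non-overlap) and
`05_associations_and_mediation.py` (correlations, regression models,
mediation).  Each writes its tables to `results/`.  The same stages are
available from the shell via `tva-arousal {simulate,fit-tva,pui,analyze,run}`.

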