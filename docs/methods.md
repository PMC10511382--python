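# Methods

## The TVA report model

Whole report is modelled as an exponential race.  A display of six distinct
letters (alphabet A–Z without I, Q, Y) is shown for a nominal exposure τ ms,
either followed by a pattern mask or not.  The effective processing time is

    a = max(0, τ + μ·[unmasked] − t0) / 1000  seconds,

where t0 ≥ 0 is the perceptual threshold and μ ≥ 0 the iconic-persistence
prolongation that only applies to unmasked displays (masking terminates
processing at stimulus offset, so masked trials are unaffected by μ).  With
equal attentional weights across the six positions, each letter races at
rate v = C/6 and is encoded with probability p = 1 − exp(−v·a).  Encoding
is capped by the vSTM capacity draw k: the report score is
min(Binomial(6, p), k).

Capacity is a two-point mixture on adjacent integers: k = K_base with
probability 1 − K_frac and K_base + 1 with probability K_frac, so the
reported capacity K = K_base + K_frac can be fractional (e.g. 3.85).  This
is the smallest capacity family that (a) yields the fractional K values
reported in the literature and (b) stays identifiable from ~140 trials; a
free distribution over {0..6} would not be.

Partial report displays one or two letters at the corners of an imaginary
square (two-letter layouts never diagonal): 4 single-target, 8
target-plus-distractor and 4 dual-target conditions.  Item rates follow the
TVA weight rule v_x = C·w_x/Σ_z w_z over the items actually displayed, with
w_T ≡ 1 and w_D = α.  Exposures are always masked.  The observation per
trial is the number of reported targets; with at most two items the race
has closed forms:

* capacity ≥ 2 — items are encoded independently with p_i = 1 − exp(−v_i·a);
* capacity 1 — only the first finisher is selected:
  P(item i) = v_i/(v_i + v_j) · (1 − exp(−(v_i + v_j)·a));
* capacity 0 — nothing is reported.

Distractors can consume capacity but are never scored.  Positional sensory
differences are not modelled; the 16-condition layout is retained so
condition-level means remain interpretable.

## Maximum-likelihood fitting

The whole-report likelihood is the product over trials of the score pmf at
the trial's condition; trials are aggregated to per-condition score counts
first, which makes one likelihood evaluation O(7 × 7).  Each per-trial
probability is floored at 1e-12 so gross misfit yields a finite penalty
rather than −∞.

Optimization is multi-start bounded Nelder–Mead on (log C, t0, K, μ), with
K continuous in [0.5, 6] and mapped to (K_base, K_frac) = (⌊K⌋, K − ⌊K⌋);
the likelihood is continuous and piecewise-linear in K, which the simplex
handles well.  Defaults: 8 Latin-hypercube starts (seeded), bounds
C ∈ (1, 200) letters/s, t0 ∈ [0, 100] ms, K ∈ [0.5, 6], μ ∈ [0, 500] ms,
convergence tolerance 1e-6 on the log-likelihood.  μ is only estimated when
unmasked conditions are present.  Partial-report fits reuse the same
machinery for α (bounds [0, 3]); when no whole-report parameters are
supplied, C and t0 of the partial-report display are estimated jointly with
α while K is fixed at 4, because one- and two-item displays carry
essentially no capacity information.

Goodness of fit R² is the squared Pearson correlation between observed and
predicted mean scores across the exposure conditions — the convention in
the TVA literature.  It is NaN when the observed means have no variance.

At the standard design (7 × 20 trials) the fitted model explains on average
≈ 0.99 of the variance in condition means of data simulated at
control-median parameters (the test suite measures this over 100
replicates); at 2000 trials/condition, C is recovered within a few percent,
t0 within ~1 ms and K within ~0.02.

## Pupillary unrest index

The PUI pipeline mirrors the pupillographic sleepiness test convention:

1. **Artifact handling.**  Samples flagged invalid, outside plausibility
   bounds (default 1.5–9.0 mm — physiological pupil range with margin), or
   following a > 1 mm jump within one 40-ms sample are gaps; gaps are
   linearly interpolated between the nearest valid neighbours.  Gaps longer
   than 3 s (long eye closures) are recorded and the segments they overlap
   are excluded, as is any segment with > 25 % interpolated samples.  These
   two segment-level thresholds are package conventions: vendor software
   removes long blinks but its segment-exclusion rule is not public.
2. **Decimation.**  Non-overlapping means of 16 consecutive samples
   (25 Hz → 1.5625 Hz), trailing partial block discarded.
3. **Segmentation.**  82.5 s at 25 Hz spans 2062.5 samples.  Each segment
   uses 2048 samples = 128 blocks (hence 127 differences); segment origins
   advance by 82.5 s with the start index rounded to the nearest sample.
   This reproduces both the documented 127-differences-per-segment count
   and 8 segments within a 660-s recording; whether the reference
   implementation instead overlaps segments over the residual 14.5 samples
   is unknown, and this is one defensible reading.
4. **PUI.**  Per segment, Σ|Δblock means| × 60/82.5 (mm/min); the total is
   the mean over valid segments (flagged when fewer than 8).  Mean pupil
   diameter (PD) averages the non-interpolated samples.

PUI is invariant to constant diameter offsets and scales linearly with
fluctuation amplitude; both are enforced by tests.

## Synthetic data generator

The generator defines the study conditions; its defaults are not tuning
knobs.

* **Report trials** are sampled from exactly the race model above
  (per-letter Bernoulli encoding, capacity draw, random letter identities;
  partial report samples exponential finishing times and selects the first
  k finishers), so simulation and likelihood are mutually consistent — a
  law-of-large-numbers test pins the empirical condition means to the
  closed forms.
* **Pupil traces** are phenomenological: baseline − linear drift +
  random-phase slow sinusoid (default 0.1 Hz, the fatigue-wave band) +
  white noise (0.02 mm, matching the 0.05-mm device resolution scale) +
  blink gaps of 0.1–0.4 s at ~4/min and optional > 3-s dropouts.  Real
  drowsy traces have nonstationary, multi-band oscillations; passing tests
  show the *pipeline arithmetic* is right, not that the generator is a
  physiological pupil model.
* **Cohorts** use a Gaussian copula.  Target Spearman correlations ρ_s are
  converted to copula correlations 2·sin(πρ_s/6); latent normals are
  mapped to normal marginals at each group's configured mean/SD, then
  clipped to scale bounds and rounded where the instrument is
  integer-valued (fatigue 5–25, depression 0–21, sleepiness 0–24).  The
  published patient-group correlation matrix and both groups' marginal
  means/SDs are the defaults; control pupillometry is not publicly
  reported, so control PUI/PD default to a healthier profile (3.0 (1.4)
  mm/min, 7.4 (0.9) mm) and no patient-side analysis touches them.  The
  sin-transformed matrix is projected to the nearest correlation matrix if
  eigenvalue clipping is needed; a non-PSD *target* matrix is an error.
  Clipping and rounding attenuate correlations slightly (< 0.03 at the
  default settings).

The depression-scale bound deserves a note: the source instrument's
subscale runs 0–21, although descriptions sometimes state 0–24; the
generator clips at the configured bound, default 21.

An `indirect_only_mediation` switch replaces the capacity–unrest
correlation with the product ρ(K,C)·ρ(C,PUI), making the PUI→K association
run entirely through processing speed.  This is the configuration under
which the full-mediation finding is reproducible by construction: the raw
published correlation (−0.433) implies a nonzero direct partial (≈ −0.20),
which at n = 40 yields full-mediation flags in only about half of
replicates, whereas the study's own mediation found a non-significant
direct path.  The default config keeps the published matrix as printed.

## Statistics

* **Rank tests.**  Mann–Whitney U statistic (as printed by R's
  `wilcox.test`) with midrank ties; z from the tie-corrected normal
  approximation with continuity correction; effect size r = |z|/√N
  (N = both groups pooled, which reproduces published r values); an exact
  permutation p is available for small untied samples.  One-tailed
  directions are fixed a priori: patients lower on C, K, α; higher on t0,
  fatigue, depression, sleepiness.
* **Non-overlap.**  Per bootstrap replicate (default 1000), both groups are
  resampled, Gaussian KDEs (Silverman bandwidth) fitted, and
  1 − ∫min(f, g) computed on a common grid extended 50 % beyond the data
  range; the estimate is the replicate mean.
* **FDR.**  Benjamini–Hochberg step-up, applied per result family (group
  tests; correlation matrix; model fits) since a single pool across
  heterogeneous analyses is the more aggressive and less conventional
  reading.
* **Regression.**  OLS; standardized betas from the z-scored fit;
  percentile case-resampling bootstrap CIs (1000 replicates, seeded);
  f² = R²adj/(1 − R²adj) — computed from the *adjusted* R², which is the
  definition consistent with published example values (a perfect fit
  reports f² = ∞ rather than an error).  Nested models are compared by the
  extra-sum-of-squares F-test; a reduced model that already fits perfectly
  short-circuits to F = 0, p = 1 to avoid 0/0 float noise.
* **Mediation.**  Simple three-variable mediation with OLS paths; indirect
  = a·b with percentile bootstrap CI over case resamples; "full mediation"
  = direct CI covers 0 while the indirect CI excludes 0.  The linear
  decomposition total = direct + indirect holds exactly on any dataset and
  is asserted to 1e-8.

## Problem sizes and reproducibility

Package defaults follow the study design (7 × 20 and 16 × 18 trials,
n = 40 per group, 1000 bootstrap replicates).  Replicate-based checks in
the test suite use 50–100 seeded replicates; the parameter-recovery check
uses 2000 trials/condition.  Every stochastic routine takes an explicit
seed (numpy `default_rng`), generators are byte-reproducible under a fixed
seed, and the CLI `run` command writes a manifest with per-stage seeds and
output hashes.

## Known limitations

* The capacity mixture and the single shared μ for both unmasked conditions
  are conventions; other capacity distributions or per-condition
  persistence values are observationally close at 140 trials.
* Letter confusability, response bias and intrusion errors are not
  modelled; scoring counts reported letters present in the display.
* The partial-report likelihood conditions only on reported-target counts;
  it does not model which position was reported.
* The pupil generator is not mechanistic (no locus-coeruleus dynamics); it
  exists to exercise the PUI pipeline and cohort-level correlation signs.
* The cohort copula reproduces pairwise rank correlations and marginals,
  not higher-order structure of real patient data.
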