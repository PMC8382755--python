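# Methods

## Pipeline model and assumptions

The package implements a five-stage chain.

1. **Stream segmentation** (`rivalry`).  A rivalry run is a sequence of
   key-state events (`cw`, `ccw`, `mixed`, `none`) with a per-run mapping of
   grating orientation to eye.  Segmentation produces contiguous half-open
   intervals `[onset, offset)`; the state of an event holds until the next
   event; time before the first informative report is missing; the final
   interval is right-censored by the run end.  Preprocessing then applies, in
   order: (a) missing time is assigned to the subsequent percept, (b) eye
   responses shorter than `min_duration` (default **0.2 s** — below a
   plausible motor press-release cycle, so treated as key bounce) are deleted
   — same-label flankers merge into one phase, otherwise the vacated interval
   is missing and falls under rule (a) — and (c) mixed and residual missing
   time are moved to an accounting record.  Adjacent same-label phases are
   always coalesced: a key release or re-press inside one percept does not
   split the phase.  These rules make the kept eye-phase time plus mixed plus
   residual missing time an exact partition of the run.

2. **Eye dominance** (`dominance`).  Phase-duration distributions are heavily
   right-skewed, so per-eye central tendency is the sample median of durations
   pooled across the subject's runs (pooling rather than averaging per-run
   medians maximises the per-eye sample at ~3 runs).  Censored phases are
   excluded from duration samples by default (right-censoring biases medians
   downward); time-based ratios (suppression, mixed fraction) use all surviving
   time including censored phases.  Dominance goes to the strictly larger
   median; an exact tie is refused rather than silently broken.  EDI is
   reported in percent.

3. **Metabolite corrections** (`mrs`).  Water-referenced estimates receive the
   CSF partial-volume correction `M/(1−f_CSF)` (CSF carries no metabolite
   signal) and then the α-correction with **α = 0.5** (white matter assumed to
   carry half the grey-matter GABA concentration), normalised to the group
   tissue fractions.  The GM/WM fractions enter the α step *as measured* (not
   renormalised after CSF removal); a `renormalise_csf` switch provides the
   alternative reading.  tCr referencing is a plain ratio — it already controls
   for tissue composition — and no relaxation correction is applied anywhere.
   The CRLB screen operates on the cohort mean CRLB per metabolite (default
   threshold **30 %**, exclusion at or above the threshold), with an optional
   per-spectrum mode.

4. **Interocular metric** (`interocular`).  `(N_DE − N_NDE)/N_NDE`, applied to
   levels computed across both stimulus blocks for the main analysis; the
   stimulus-contrast control first forms checkerboard−fixation per eye and
   then applies the same ratio, flagging subjects with a non-positive NDE
   delta as undefined (excluded pairwise, counted in the report).

5. **Inference** (`inference`, `cohort`).  Shapiro–Wilk at 0.05 gates each
   variable; a correlation uses Spearman when either variable fails the gate,
   Pearson otherwise; paired comparisons gate on the differences.  The cohort
   battery is exposed statsmodels-style: `CohortAnalysis` (model built from
   the dominance and corrected-levels tables) → `fit()` →
   `CohortAnalysisResults` with the analysis table, exclusion accounting and a
   `summary()` report.  No multiple-comparison correction is applied; the
   report prints the number of tests.

## Exact Spearman p-values

The two-sided p is the probability, over all n! orderings of one variable,
that |r| of the rank vectors is at least the observed |r| minus a tolerance of
1e−12 (guarding float jitter in rank correlations).  Three routes:

* n ≤ 9 — direct enumeration over cached permutation arrays (average ranks,
  so tied data are handled);
* tie-free n ≤ 13 — the exact null of S = Σ(Rᵢ−i)² by dynamic programming
  over subsets of assigned ranks: state = set of used ranks, payload = count
  vector over partial S.  This reproduces enumeration exactly (cross-checked
  at n = 8) at 2ⁿ·n vector operations instead of n! permutations, and the
  n = 12 null used by the cohort battery is built once and cached;
* otherwise — seeded Monte-Carlo with 10⁶ permutations and the add-one
  estimator (count+1)/(m+1), which keeps p in (0, 1]; a seed is mandatory on
  this route and is embedded in the report.

## The synthetic-data generator

`simulate` emulates the study design: 12 subjects, 3 × 180 s rivalry runs,
and a metabolite table with DE/NDE/rest viewing conditions ×
all/checkerboard/fixation blocks for GABA and tCr, plus voxel tissue
fractions and per-eye %BOLD values.

**Phase durations** are gamma distributed per eye (the standard family for
bistable-percept dominance durations; only right-skew is essential and the
family sits behind one interface).  Defaults: shape 6 for both eyes and an
NDE median of 1.6 s; the dominant eye's scale is larger in proportion to the
subject's true EDI (the gamma median is linear in scale at fixed shape, so the
scale ratio sets the EDI exactly).  The shape/median pair was calibrated once,
at design time, so that median-estimation noise over a 3 × 180 s session
stays as small as a defensible rivalry model allows (see *Limitations*).
Mixed interludes occur at transitions with probability 0.15 and exponential
mean 0.6 s; reports are delayed by an exponential motor latency of mean
0.2 s, and a phase's report becomes `none` with probability 0.03, exercising
the missing-data rule.  A report overtaken by the next phase's report is
dropped (fast phases can be skipped entirely, as with a real observer).

**Traits.**  True EDI is gamma distributed with mean 7.9 % and SD 8.2 % (the
cohort statistics of the population this emulates); the true interocular GABA
is normal with mean 0.03 and SD 0.05 (consistent with a positive but
non-significant DE−NDE trend at n = 12 and between-subject GABA:H₂O of
0.91 ± 0.12).  The two traits are coupled through a Gaussian copula whose
correlation is chosen as 2·sin(π·ρₛ/6) so that `latent_effect` is the target
Spearman correlation.  Tissue fractions are drawn near GM/WM/CSF =
0.438/0.50/0.062 and renormalised to the simplex; CRLBs near 28.1 ± 3.7 % for
GABA.  Metabolite noise is additive Gaussian (default SD 0.01) on the
water-scaled value, truncated at zero; no spectral-fitting physics is
modelled.  The water-scaled values are constructed by *inverting* the CSF and
α corrections at the cohort's own group means, so with zero noise the
corrected pipeline output equals the simulated tissue-level concentration to
machine precision — the basis of the round-trip tests.

**Condition labels follow the behavioural assignment.**  As in the emulated
design, the scanner's DE/NDE conditions are assigned from the prior
psychophysics session: the generator parses its own simulated runs and labels
the metabolite conditions by the *measured* dominant eye.  The ground truth
therefore records both the latent interocular value and the value under the
labels actually used (which flips to −i/(1+i) when the behavioural assignment
disagrees with the latent dominant eye).  With degradations off the two
coincide in practice, and parsing a noise-free stream reproduces the generated
phases exactly.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: serial dependence and slow drifts in rivalry dynamics,
adaptation across runs, response-hold errors other than uniform dropout,
spectral-fit bias and CRLB–value covariance, BOLD contamination of
linewidths, and any coupling of %BOLD to dominance (the simulated %BOLD is
deliberately null).

## Numerical choices

Intervals are half-open in seconds; comparisons of permutation statistics use
the 1e−12 tolerance above; gamma medians are obtained by Brent root-finding on
the CDF (xtol 1e−12); tissue fractions must sum to 1 within 1e−6; the
mixed-fraction screen excludes at ≥ threshold (default 50 % of reported time,
this package's choice — the emulated design excluded a single extreme
participant rather than stating a cut-off); degenerate inputs (constant
samples, all-zero paired differences, zero-variance correlates) produce
explicit warnings/flags or recorded skips, never silent answers.

## Limitations

**EDI measurement noise bounds what a 12-subject study can detect.**  The
standard error of a sample median is 1/(2·f(m)·√n); with ~150 phases per eye
per session and gamma-like durations this puts the session-level EDI noise at
several percentage points — the same order as the trait spread (SD ≈ 8 %).
Because the measured EDI is folded at zero (dominance is re-assigned from the
same data), its rank reliability is further reduced.  Consequently, even a
true trait coupling of 0.8 yields an observable Spearman correlation well
below it, and the per-cohort probability of an exact p < 0.05 at n = 12 stays
in the minority — the acceptance suite measures this directly
(`test_null_calibration_and_power`), and the package treats it as a property
of the design, not a defect of the estimator.  Single significant
correlations at this sample size should therefore be read with caution.

**Assignment-induced confound.**  When dominance assignment is noisy and the
DE−NDE response difference has a nonzero mean, label flips for weakly
dominant subjects alone induce a spurious positive correlation between EDI and
the interocular metric.  The null-calibration test controls for this by
setting both the latent coupling and the mean interocular shift to zero; real
studies with this design inherit the confound.

**Other limitations.**  Tissue fractions are consumed, not computed; the
%BOLD inputs are externally supplied; the rivalry preprocessing rules are
deterministic design choices where the emulated procedure was underspecified
(rule order a→b→c, coalescing of same-label phases, censored-phase exclusion)
— each is covered by the brute-force oracle tests so the contract is at least
explicit.
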