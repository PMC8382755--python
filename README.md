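# eyegaba

Analysis pipeline linking **sensory eye dominance**, measured behaviourally with
binocular rivalry, to **interocular differences in GABA** quantified with
magnetic resonance spectroscopy (MRS) in the early visual cortex.  It is aimed
at visual psychophysicists and MRS researchers who need a tested, reusable
implementation of this analysis chain — from raw keypress logs and
spectral-fit tables to the cohort-level inferential report — together with a
synthetic-data generator so every stage can be validated without access to
participant data.

## What it computes

**Eye dominance.**  During binocular rivalry the observer continuously reports
which eye's grating is perceived.  The keypress stream is segmented into
percept phases; missing data before a transition is assigned to the subsequent
percept, responses shorter than 200 ms are removed, and mixed/missing time is
excluded from duration statistics but retained in a time-accounting record.
Because phase durations are heavily right skewed, per-eye central tendency is
the *median* phase duration, pooled across a subject's runs.  The eye with the
longer median is the dominant eye (DE), and dominance strength is the eye
dominance index

    EDI = 100 · (d_DE − d_NDE) / d_NDE   [%]

with d_DE, d_NDE the DE and non-dominant-eye (NDE) median phase durations.
Two auxiliary quantities come from the accounting: the perceptual suppression
ratio `dominant / (dominant + mixed)` and the mixed-percept fraction used to
screen out participants dominated by piecemeal percepts.

**Metabolite levels.**  Water-referenced spectral-fit estimates are corrected
for CSF partial volume, `M / (1 − f_CSF)`, and for grey/white composition with
the α-correction

    c_corr = c / (f_GM + α·f_WM) · (μ_GM + α·μ_WM) / (μ_GM + μ_WM),   α = 0.5,

where μ are group-mean tissue fractions ("GABA:H₂O").  Alternatively the
metabolite is referenced to total creatine ("GABA:tCr"), which needs no tissue
correction.  Metabolites whose mean Cramér–Rao lower bound across the cohort
exceeds 30 % are screened out.

**Interocular metric.**  For any per-eye neural response N (GABA level, %BOLD
change): `(N_DE − N_NDE) / N_NDE` — the fractional difference between
dominant- and non-dominant-eye viewing; scale invariant, hence independent of
the referencing route.

**Inference.**  Every test is gated by Shapiro–Wilk normality (p < 0.05 →
non-parametric).  Correlations use Spearman's rank coefficient with a
*two-sided exact permutation p-value* (full n! enumeration for n ≤ 9; an exact
subset-DP distribution of S = Σdᵢ² for tie-free larger n; seeded Monte-Carlo
otherwise) or Pearson's r; paired comparisons use the paired t or Wilcoxon
signed-rank test.  α = 0.05, uncorrected; the report states the number of
tests run.

## Worked example

Simulate a study-sized cohort (12 subjects, 3 × 180 s rivalry runs each,
metabolite/tissue tables) with a strong built-in rank coupling (0.8) between
the true EDI and the true interocular GABA, then run the whole chain:

```python
import eyegaba as eg

data = eg.simulate_cohort(eg.CohortSimParams(seed=3, latent_effect=0.8))
res = eg.analyze(data.runs_by_subject, data.metab, data.tissue, data.bold,
                 config=eg.AnalysisConfig(seed=3))
print(res.results.summary())
```

```
Cohort analysis: eye dominance x interocular GABA
==========================================================
subjects analysed: 12
alpha = 0.05 (uncorrected), 16 tests run
mixed-percept screen >= 50.0% of reported time
undefined interocular ratios excluded pairwise: 0
seed: 3
----------------------------------------------------------
analysis                              method                    stat        p   n
d_DE vs d_NDE median phase duration   wilcoxon_signed_rank     0.000   0.0005  12 *
DE vs NDE GABA:H2O                    wilcoxon_signed_rank    19.000   0.1294  12
EDI ~ interocular GABA:H2O            spearman                 0.552   0.0667  12
EDI ~ DE GABA:H2O                     spearman                 0.259   0.4169  12
EDI ~ NDE GABA:H2O                    spearman                 0.119   0.7160  12
...
```

Reading the output: DE median phase durations exceed NDE medians in every
subject (the Wilcoxon row, p = 0.0005 — dominance is real by construction);
the main analysis row gives the Spearman correlation between EDI and
interocular GABA:H₂O with its exact permutation p (here r = 0.55, p = 0.067 —
at n = 12 even a strong latent coupling is frequently attenuated below the
significance threshold by median-estimation noise; see `docs/methods.md`).
Per-subject dominance details live in `res.dominance`:

```
subject     d_de    d_nde dominant_eye   edi_pct  suppression  mixed_fraction_pct
    S01 2.067950 1.734027        right 19.257090     0.928703            4.033973
    S02 1.721110 1.631321        right  5.504029     0.835305            9.230271
    S03 1.968525 1.698549         left 15.894512     0.909362            5.030058
```

The same chain is available from the shell (`eyegaba simulate`, `eyegaba
parse`, `eyegaba dominance`, `eyegaba correct`, `eyegaba interocular`,
`eyegaba report`); run `eyegaba --help` for the file dialects.

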