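# Methods

## The brain-age model

The score condenses 12 regional brain volumes into an age-like number
confined to chronological age ± θ years. The chain is:

1. **Normative adjustment.** For every (ROI, sex) stratum of a cognitively
   unimpaired (CU) reference sample we fit an ordinary least-squares
   regression of volume (mL) on age (years) and keep the standardized
   residuals. A subject's volume becomes z = (v − v̂(age)) / σ̂ with
   σ̂ = √(SS_res / (n − 2)), and a percentile p computed by the mid-rank
   convention rank/(n + 1) against the stored reference residuals, so p
   never reaches 0 or 1. Linear-in-age per sex is deliberately the minimal
   normative model: the adjustment's purpose is fairness of the tail rule
   across age and sex, not prediction. No intracranial-volume normalization
   is applied. Thresholds for the abnormal tail use the linear-interpolation
   empirical quantile of the reference residuals.

2. **Weights.** Each region's weight is |Cohen's d| (pooled-SD standardized
   mean difference) between the cognitively impaired (CI) group and the CU
   reference on the adjusted scale, normalized to sum to one. The CI arm is
   the study cohort itself; the CU arm is the reference sample. If no region
   differs at all, weights degrade to uniform with a warning rather than
   failing, so null-data pipelines run to completion.

3. **Atrophy rule.** A region is *atrophic* when its adjusted percentile
   falls strictly inside the abnormal 5% tail — the bottom tail for
   structures that shrink with atrophy, the top tail for the inferior
   lateral ventricles, which expand as the surrounding tissue is lost. A
   percentile exactly on the boundary does not flag. The continuous
   companion of the flag is the severity s_c = 1 − p (or p for expanding
   regions), which puts all regions on a common [0, 1] scale so the
   weighted sum G = Σ w_c s_c is well defined.

4. **Gap and brain age.** Presence of at least one atrophic region selects
   the ageing branch g = +G; absence selects g = −(1 − G). Brain age is
   BA = age + θ·g with θ = 7 by default, hence |BA − age| ≤ θ by
   construction, and the three encodings (branch, sign of g, any-flag) are
   provably consistent: a flagged region has severity > 0.95, so G > 0 on
   the ageing branch, and G < 1 strictly when no region is flagged. A
   subject is "older by brain age" iff BA > age; the tie BA = age is
   classified younger, the conservative choice for any claim about the
   older group's risk. The exact closed form of this chain is one concrete
   instantiation of the published verbal description (weights from CU/CI
   differences, bottom-5%-tail atrophy flags, BA_up/BA_down branching,
   ±θ bound); any alternative algebra satisfying the same constraints can
   be swapped in behind the same function contracts.

## Statistical machinery

- **Test selection** mirrors clinical-table practice: Shapiro–Wilk per
  group and Levene's test (both at α = 0.05, Levene centered on means)
  route two-group continuous comparisons to Student's t, Welch's t, or
  Kruskal–Wallis; three or more groups always use Kruskal–Wallis;
  dichotomous variables use Pearson's χ² without continuity correction.
  Covariate adjustment of these comparisons is deliberately not performed.
- **Multiplicity**: Benjamini–Hochberg step-up adjustment, the family being
  the variables of one reported table, not the whole run.
- **Correlations**: Spearman's rho with mid-rank tie handling,
  pairwise-complete over missing scores, two-sided p from the t
  approximation; constant variables yield missing cells.
- **2×2 effect**: the unconditional odds ratio (a·d)/(b·c) with a Wald CI
  exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)); any zero cell triggers the
  Haldane–Anscombe +0.5 correction, flagged in the result. On the four-group
  table (22, 34, 3, 32) this yields 6.90 (1.88, 25.31).
- **Survival**: event = conversion; administrative censoring at exactly 36
  months. Kaplan–Meier product-limit curves (censoring tied with an event
  handled censored-after-events), the k-sample log-rank test, and a Cox
  proportional-hazards fit with Efron tie handling (appropriate at
  clinic-visit time resolution) and Wald CIs on the log hazard ratio. The
  stratified analysis crosses sex with education dichotomized at 12 years,
  and then additionally with brain-age direction (4- and 8-group designs);
  empty cells are dropped with a warning and small strata flagged. Time
  origin is months since baseline; any consistent origin preserves the
  comparisons.

## The synthetic cohort generator

The generator emulates the statistical structure of a 91-subject
amyloid-negative amnestic MCI cohort: four designed subgroups
(younger/older by brain age × non-converter/converter of sizes
22/34/3/32), age at scan 72.04 ± 9.10 (non-converters) vs 74.51 ± 7.18
years (converters) truncated to the ≥ 50-year inclusion range, K-MMSE
26.25 ± 3.90 vs 23.17 ± 4.20 (integer, clipped to 0–30), female fractions
51.79% vs 68.57%, education 9.62 ± 5.43 years, conversion times uniform on
(0, 36] months, censoring at 36. Neuropsych scores get converter shifts
only where subgroup differences are expected (CDR-SOB, RCFT
delayed/recognition, COWAT animal, ideomotor praxis); other domains differ
only by noise. Regional volumes come from the same linear age + sex +
Gaussian-noise family the normative module fits, at plausible adult
volumes (e.g. hippocampus ≈ 3.5 mL, per-hemisphere frontal lobe ≈ 75 mL).

Two design choices matter for interpretation:

- **Designed direction, recoverable by scoring.** Older-by-design subjects
  have 1–3 (non-converters) or 2–6 (converters) regions forced into the
  abnormal tail at |z| ≥ 2.5 past the mean; all other study-cohort noise is
  truncated to the healthy band |z| ≤ 1.0. Because the empirical
  5th-percentile threshold from a 600-subject reference has a sampling SD
  of ≈ 0.1 on the z scale, both margins are many standard errors wide and
  scoring recovers the designed direction essentially deterministically —
  which is what lets the worked example reproduce the 22/34/3/32 table
  exactly. Real cohorts have no such margin: near-threshold subjects would
  classify with noise, so exact-count reproduction is a property of the
  synthetic design, not a claim about real data. The `null_atrophy` switch
  removes all truncation, in which case roughly 1 − 0.95¹² ≈ 46% of
  subjects flag at least one region by chance alone.
- **Two conversion modes.** `designed` fixes the subgroup sizes exactly
  (the observed-table structure); `stochastic` keeps the direction margins
  (66 older / 25 younger) and draws conversion per subject at the
  per-direction rates 32/66 and 3/25, optionally boosted per sex ×
  education stratum. The stochastic mode exists because fixed subgroup
  sizes make the 2×2 degenerate across replicates; binomial sampling is
  what gives the recovery experiment's Wald CI a meaningful coverage.

Moments stated as mean ± SD are those of the generating normal before
range truncation; the ≥ 50-year age floor and score bounds shrink realized
SDs by up to ~5% (the truncated-normal moments are the exact oracle, and
realized means stay within 2% of the configured values).

## Recovery experiment

Each replicate generates a stochastic-conversion cohort, fits a fresh
normative reference, scores, classifies, and computes the conversion odds
ratio with its 95% Wald CI. At the default configuration (true OR ≈ 6.90)
the mean log-OR over 200 replicates sits within 15% of the truth. The Wald
interval itself is mildly conservative here: with 25 subjects in the
younger arm at rate 0.12, the zero-cell probability is ≈ 4% and the
Haldane-corrected interval's exact coverage is ≈ 97% (computable in closed
form from the binomial 2×2), rather than the nominal 95% it attains in
better-balanced designs such as the true-OR = 1 configuration.

## Problem sizes and numerical choices

Default sizes: 91-subject cohort, 600-subject reference (≥ 10 per sex
stratum enforced), 200 recovery replicates, 1000-replicate type-I-error
simulations, 10,000-subject bound checks. Degenerate inputs are handled
explicitly: zero residual variance raises rather than silently producing
infinite z; missing ROI volumes exclude a subject from scoring (with a
warning) but not from the clinical table; rank-deficient Cox designs are
rejected before fitting. Cohort CSVs write floats in shortest round-trip
representation, so write→read is exact and byte-deterministic.

## Limitations

Volumes arrive as a table; segmentation, imaging and PET-based amyloid
status are entirely out of scope. The 12-region panel is a configurable
stand-in assembled from the regions implicated in amnestic MCI volumetry.
The generator's uniform event-time distribution and
group-membership-driven conversion are simplifications — no latent hazard
model, no visit-interval discretization — adequate for calibrating the 2×2
and KM stages, not for studying time-to-event shape. Passing tests
demonstrate internal consistency and correct statistical machinery on
cohorts with the designed structure, not clinical validity on real
patients.
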