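# Methods

## The problem

Clinical variant classification under the ACMG/AMP framework uses
computational predictors as one line of evidence (criteria PP3/BP4).  If
those predictors were systematically less accurate for non-European
genomes, their clinical deployment would propagate that inequity.  Judging
the question requires care: allele frequency (AF) is a strong confounder,
because very rare variants are both enriched for true pathogenicity and
predicted more confidently, and ancestry groups differ sharply in their
rare-variant AF mixtures (the European share of reference databases is far
larger, so European variant sets reach much lower frequencies).  `vepfair`
evaluates predictor fairness the way the confounding demands: stratified by
AF, with an explicit detector for the aggregate-vs-binned (Simpson)
reversal.

Real inputs of this kind (biobank exomes, gnomAD per-population AFs,
ClinVar/HGMD labels) are access-controlled, so the package pairs the
evaluation machinery with a synthetic-cohort generator whose every feature
has a closed-form expectation.  The pipeline runs identically on user data
supplied as TSV or VCF.

## Synthetic cohort model

**Allele frequencies.** Each ancestry has `n_sites_present` segregating
sites with AF drawn from a truncated power law, density `∝ x^-α` on
`[af_min, af_max]`, sampled by inverse CDF.  `α = 1` (the default) is the
log-uniform law — equal mass per frequency decade, a neutral-SFS-like
shape; larger `α` shifts mass toward rarer variants.  `af_max ≤ 0.01`
enforces the rarity cutoff at generation time.  Site sharing across
ancestries is deterministic: the first `round(s·n_total)` sites are present
in every ancestry (`s` = `shared_site_fraction`), the remainder are private
blocks, and the accounting `n_shared + Σ(n_present − n_shared) = n_total`
is validated.  Shared sites draw independent per-ancestry AFs from their
own laws; cross-ancestry AF correlation (shared demography) is out of
scope.

**Labels.** `P(pathogenic | AF) = logistic(a + b·log₁₀ AF)` with `b < 0`
encoding "rarer is more likely deleterious".  For sites present in several
ancestries the model consumes the geometric mean of the present AFs (the
natural summary for a model linear in log AF).  Synonymous sites are
neutral controls and never pathogenic.

**Scores.** For each predictor, latent score `~ N(μ_benign + d(AF)·y, σ²)`
where `y` is the true label and the separation `d(AF)` is a nonincreasing
step function of AF, so discrimination declines as variants become common.
The implied AUC within an AF bin is `Φ(d/(σ√2))`, the binormal closed form
used as ground truth.  Latents are squashed to `[0, 1]` by a fixed logistic
map centered at `μ_benign + d_max/2` with scale `σ`; the map is monotone,
so every rank statistic (AUC, threshold intervals after the same
transform) is unchanged, and the scale is chosen so simulated scores span
enough of `[0, 1]` to exercise calibrated evidence tiers at both extremes.

**Conservation.** `~ N(mean_by_label + af_slope·log₁₀ AF, sd²)`, a
GERP++-rank-like covariate.  It is generated and summarized descriptively
but never fed into scores: conservation here is an explanatory covariate,
not a model input.

**Genotypes.** Per individual and site, dosage `~ Binomial(2, p)`
independently (no linkage, no inbreeding), so the heterozygosity
probability is `2p(1−p)` and the expected per-genome het burden is
`Σ_v 2p_v(1−p_v)`, with per-person variance `Σ h(1−h)` — the analytic SE
used by the recovery checks.

**Seeding.** One master seed per cohort; each generation stage (AFs,
consequences, labels, scores per predictor, conservation, genotypes)
consumes its own spawned substream in fixed order, so adding a stage never
perturbs earlier draws, and identical specs produce bit-identical cohorts.

### What the generator does and does not emulate

It reproduces the statistical structure the evaluation depends on: unequal
sample sizes and site counts, ancestry-specific rare-AF mixtures,
AF-dependent pathogenicity and discrimination, label-correlated
conservation, and per-person heterozygous burdens.  It does not attempt
coalescent or demographic realism, linkage, homozygous burden,
X-chromosome dosage, cross-ancestry AF correlation, or predictor-specific
score idiosyncrasies.  Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated under the stated statistical
conditions — not that any particular real predictor is fair or unfair.

## Dataset-construction conventions

- **Rarity filter**: retain a variant iff its maximum AF over ancestries
  where it was observed is strictly `< 0.01`; variants observed nowhere are
  dropped.  AF exactly 0.01 is excluded ("below 1%").
- **Missing AF ≠ AF 0**: a missing entry means "not observed in that
  ancestry's reference"; observation (AF > 0) defines ancestry membership,
  and membership subsets may overlap.  VCF writers often emit 0 where they
  mean unobserved; an explicit 0 survives IO but never confers membership.
- **Labels**: positives are ClinVar pathogenic / likely pathogenic (and
  combinations) plus HGMD DM; negatives are benign / likely benign.  On
  conflict the ClinVar designation is retained.  HGMD "DM?" is not treated
  as pathogenic.  Everything else is unlabeled.
- **Training-set exclusions** apply per predictor, only to that predictor's
  evaluation; a predictor without a list keeps all variants.
- **Coordinates** are 1-based VCF convention; multi-allelic records are
  decomposed one row per alternate allele with per-allele INFO entries.

## Evidence mapping

Calibration tables map score intervals to evidence points: +1/+2/+3/+4 for
PP3 supporting/moderate/moderate/strong, negatives for BP4; scores between
the calibrated benign and pathogenic regions are indeterminate (0 points).
Pathogenic tiers are closed at their minimum score (`score ≥ threshold`
qualifies) and benign tiers at their maximum — published threshold tables
state bounds as ≥/≤, and since tables are configuration, either reading of
a specific predictor can be encoded by nudging a value.  Tables are
validated at load time (tier ordering, region disjointness), never at call
time.  A missing score yields a missing assignment, never indeterminate.
The shipped `data/example_calibration.yaml` is illustrative — shaped like
ClinGen-style calibrations but not a verified transcription of them — and
omits BP4-strong, which many predictors never reach.

## Burden statistics

Heterozygous means dosage exactly 1; homozygous-alternate sites are not
counted.  `mean_af` uses the individual's own ancestry's AF for each het
site (whether a per-person mean AF should use ancestry-matched or global
frequencies is genuinely open; ancestry-matched is implemented).  Sites
with missing conservation are excluded from `mean_conservation`; per-person
evidence yields count categories over het missense sites that carry a
score, so counts + missing-score sites = het missense count.  Individuals
with zero het sites are included in summaries (means/medians over all
individuals), with their means recorded as missing.  Summary quartiles use
linear interpolation between order statistics (numpy default) — stated
because boxplot reproduction depends on it; SD uses the n−1 denominator.

## Fairness evaluation

- **AUC** is the Mann–Whitney statistic with half credit for ties,
  computed by ranking; it equals the trapezoidal ROC area.  An empty class
  yields a missing value, never an exception in batch mode.
- **Binning** is on each ancestry's own AF, half-open `[lo, hi)` over
  `(0, 0.01)`; default interior edges `1e-5, 1e-4, 1e-3` (four bins), fully
  configurable and echoed into every output, because published AF-binned
  evaluations rarely state their edges.
- **Bootstrap**: `B` iterations (default 1,000); each iteration resamples
  variants with replacement independently within every (ancestry × AF bin)
  stratum, preserving stratum sizes.  The aggregate ("all") resample is the
  union of the per-bin stratum resamples, so it is AF-stratified too.
  Variants, not individuals, are resampled: the units of the comparison are
  labeled variants.  Iterations where a stratum loses a class yield a
  missing AUC for that stratum-iteration.
- **Empirical p** is one-sided: the fraction of paired iterations in which
  the comparison ancestry's AUC strictly exceeds the reference's, with
  missing-AUC iterations dropped from numerator and denominator.  Pairing
  is within iteration index; the reference and comparison resamples are
  independent draws.  An optional `(k+1)/(m+1)` estimator exists and is off
  by default.
- **Minimum-count gate**: an AUC (and hence a p-value) is reported only
  when the cell has ≥ 10 positives and ≥ 10 negatives (configurable); gated
  cells carry an explanatory reason.
- **Bonferroni**: the family size defaults to the number of p-values
  actually computed per predictor grid and is always user-settable;
  published divisors for such grids are typically not derivable from the
  figure, so the divisor is configuration recorded in the output.
- **Simpson detection**: a (predictor, ancestry) pair is flagged iff the
  aggregate comparison is significant after correction while no per-bin
  comparison is, using the corrected criterion at both levels —
  symmetric, and conservative against flagging on a single noisy bin.

## Replicated experiments (study conditions)

`vepfair.experiments` fixes the configurations shared by the analysis
drivers, the test suite, and `scripts/acceptance.py`:

- **AUC oracle**: 1,000 random instances with class sizes ≤ 8 on a coarse
  score grid (tie-rich), checked exactly against O(n²) pair enumeration.
- **Binormal recovery**: `d/σ ∈ {0, 0.5, 1, 2}`, 2,000 variants per class,
  empirical AUC inside the 99% Hanley–McNeil CI of `Φ(d/√2)`.
- **Het-burden recovery**: 5,000 individuals × 1,000 sites; simulated mean
  within 3 analytic SEs of `Σ 2p(1−p)`.
- **Null calibration**: two ancestries, identical log-uniform AF laws and
  score models, 1,000 labeled variants each, balanced classes, B = 200,
  500 replicates; raw rejection rate at α = 0.05 pooled over all comparison
  cells.
- **Simpson reversal**: identical per-bin score models with theoretical bin
  AUCs 0.95/0.85/0.75 (σ = 1, `d = √2·Φ⁻¹(AUC)`), AF laws `α = 1.5` (EUR,
  rare-shifted: ~71% of variants below 1e-4) vs `α = 0.5` (comparison,
  common-shifted: ~93% above 1e-3), 5,000 variants per ancestry, B = 200,
  100 replicates.

The null and Simpson cohorts use a flat label model (intercept 0, slope 0)
so classes are balanced and the per-bin AUCs are exactly the designed
values — a controlled experiment; the demonstration cohort keeps the
AF-dependent label model.  These problem sizes were chosen so each
experiment completes in about a minute on one CPU while leaving the
binomial/bootstrap standard errors well inside the decision bands.

## Known limitations

- Aggregate-AUC theory is not closed-form under mixed-AF sampling (cross-bin
  score pairs), so aggregate expectations are checked by simulation only.
- The bootstrap compares independent resamples paired by iteration index;
  whether published analyses pair draws or compare independent resamples is
  usually unstated, and the choice affects p-value granularity at small B.
- Per-bin AUC control on shared sites is approximate when score models
  consume the cross-ancestry geometric-mean AF; experiments avoid this by
  using disjoint sites.
- DeLong-style analytic AUC variance, calibration (reliability) analysis,
  and multi-reference all-pairs comparisons are deliberately out of scope.
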