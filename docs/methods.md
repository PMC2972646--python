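# Methods

## Phenotype construction

The bulimia-nervosa symptom count (BNSC) is the sum of eleven interview
items: the binge-eating entry question (0/1), six compensatory behaviours
(vomiting, laxatives, water pills, exercise, fasting, strict dieting; 0/1
each), loss of control during the binge (0–3), amount eaten (0–2), concern
about weight and shape (0–3), and whether binge eating and vomiting occurred
in the same episodes (0/1).  The interview's skip structure makes the entry
question authoritative: non-endorsers score 0 on everything downstream, so a
skipped item is absence, not missingness.  The structural maximum is 16; the
empirical range in the population the generator emulates is 0–11, and we
treat 11 as an empirical, not structural, bound.  A missing item inside an
endorsed section is zero-filled with a logged warning by default
(`missing_policy="strict"` raises instead), because the skip logic reads
absence as zero.

Broad BN is a lifetime diagnosis at either interview wave (OR across waves,
missing treated as no unless both waves are missing).  Broad AN is the OR of
three definitions (strict criteria; criteria without amenorrhea; criteria
without the body-image item).  The any-illicit variable ORs six substances
(cannabis, sedative, stimulant, cocaine, opiate, hallucinogen); regular
smoking is an average of at least seven episodes per month (inclusive).
Onset chronology compares integer onset ages (ED-first / SUD-first / same);
individuals missing either age are excluded and tallied.

## Phenotypic association stage

2×2 tables get the uncorrected Pearson chi-square (a Yates flag exists but
is off, matching the analysis style emulated) and the Woolf log-scale OR CI;
zero cells are an error unless Haldane–Anscombe continuity is requested.
Regression uses independence-working-model logistic maximum likelihood with
the cluster-aggregated sandwich variance, clustering on the family id — the
standard reduction of GEE for twin data.  With singleton clusters this
reduces exactly to the HC0 heteroskedasticity-robust estimator (tested
against an independent implementation at 1e-8).  Significance uses the
conservative fixed α = .01 convention; no FDR procedure.  Table percentages
are half-up integer percents.  Two printed cells in the source table this
stage emulates (illicit 39% where 8/21 rounds to 38; caffeine 70% where 9/13
rounds to 69) deviate from exact arithmetic; we implement exact arithmetic
and document the discrepancy rather than reproduce it.

## Twin models

Liability-threshold A/C/E models are fitted by full-information ML on
ordinal raw data.  The implied correlation matrix for a complete pair is

    [ A + C + E     κA + C   ]
    [ κA + C      A + C + E  ]      κ = 1 (MZ), 0.5 (DZ)

with per-component matrices built from the Cholesky paths.  A pair's
likelihood is the MVN rectangle probability between the observed categories'
thresholds; singletons and missing phenotype values drop dimensions, which
is the exact marginal likelihood.  Dimensions 1–2 use exact formulas (error
function; Owen's-T bivariate CDF); 3–4 use a batched Genz
sequential-conditioning quasi-Monte Carlo rule on a fixed scrambled Sobol
set, so −2lnL is deterministic to the digit.  Defaults: 256 points during
optimization, 8192 for the reported −2lnL (4-D absolute error ≈ 1e-6–1e-5;
the test suite checks agreement with adaptive quadrature at 1e-5 and
probability normalization at 1e-6).

Parameterization enforces standardization exactly: variance shares go
through softmax logits with E as the baseline (so e² > 0 always — E carries
measurement error), and the trait-2 cross paths are expressed through
tanh-mapped component correlations, `a21 = r_a·sqrt(a2_2)`.  Dropped
components are structurally zero.  Diagonal paths are non-negative by
construction; correlation signs ride on the cross paths.

Thresholds default to the pooled marginal ML (inverse-normal cumulative
frequencies — the two-stage polychoric convention); joint estimation with
the paths is available via `FitOptions(thresholds="joint")`.  Two-stage was
chosen as the default because it halves the bivariate parameter count with
no visible effect on recovered components at ~1,000 pairs.  Ordinal traits
with more than 7 observed categories are collapsed into a "6+" top category
before fitting (12 sparse categories make 11 thresholds numerically
fragile); the full scale is available via `FitOptions(max_categories=None)`.

Optimization: L-BFGS-B with forward differences on the smooth deterministic
objective from a polychoric/Falconer-based start (plus a near-zero-C start
for ACE-type models and optional seeded perturbed restarts), followed by a
small-simplex Nelder–Mead polish so nested fits are ordered well below the
comparison tolerance.  Non-convergence is reported on the fit, never
silent.  Nested models are compared by Δχ² (clamped at 0 within 1e-4; a
submodel beating its parent beyond that tolerance raises, since it can only
mean the parent's optimizer failed) and ΔAIC = Δχ² − 2Δdf.  Profile CIs
re-optimize nuisance parameters along a pinned share or correlation until
−2lnL rises by the χ²(1) quantile; profiles that never cross inside the
domain return the boundary flagged (the ordinal-data analogue of intervals
spanning −1..+1).

## Synthetic cohort generator

The generator is the study-conditions oracle: per pair it draws A factors
correlated 1.0/0.5 across co-twins, shared C, independent E, maps them
through the Cholesky paths, and cuts the standardized liability at the
trait thresholds.  Defaults emulate the cohort the analysis assumes:
600 MZ + 440 DZ female pairs, singleton rate 0.005, binary SUD thresholds
calibrated to prevalences 8.14% (illicit), 14% (alcohol), 23% (caffeine),
43% (regular smoking), and the published variance shares as generating
truths (BNSC AE 42/58; smoking 81/5/14; illicit 68/0/32; alcohol 53/0/47;
caffeine 27/0/73; bivariate BNSC×alcohol r_a = +0.53, r_e = −0.03).

The BNSC marginal table is a calibrated stand-in: the source reports only
mean 1.27, sd 2.5, range 0–11 and a 63% entry-question non-endorsement
rate, so counts 1..11 carry 37% mass shaped as a discretized Beta(0.325,
0.948), solved once so the full marginal has mean 1.270 and sd 2.500.  Onset
ages are rounded normals truncated to [8, 60] (ED means/sds as published;
SUD onset parameters are plausible choices, since none are published), and
the comorbid onset *ordering* is injected directly from a probability vector
(e.g. 70/15/15 for BN×alcohol) rather than emerging from a joint hazard
model — the ordering proportions are the only chronology structure the
emulated tables report.  Seeding: one master seed, per-pair counter-derived
substreams, so cohorts are reproducible under any chunking.

What the generator does *not* emulate: item-level BN responses (the
symptom count is generated directly on its marginal), age/cohort structure,
measurement unreliability beyond E, assortative mating or dominance (DZ
genetic correlation is fixed at 0.5), and sex-limitation (the design is
female–female pairs only).  Passing recovery tests therefore show the
estimation machinery is correct under the stated model, not that the model
is right for any particular real cohort.

## Small-sample behaviour of boundary-constrained ACE fits

Two recovery settings deserve a caveat that the test suite makes visible
rather than hides.  With a rare binary trait (8% prevalence) and ~440 DZ
pairs, the DZ tetrachoric correlation rests on a handful of
concordant-affected pairs and is extremely noisy; whenever the sampled DZ
correlation exceeds half the MZ correlation, the ACE ML places ĉ² > 0 and
the heritability estimate collapses toward 2(r̂MZ − r̂DZ).  The median â²
over 25 replicates sits ≈10 points below a generating a² = 0.68 — a genuine
property of boundary-constrained ML at this design, not an estimation bug
(the fit matches a grid search of the likelihood surface, and the bias
vanishes by n ≈ 30,000 pairs).  The bivariate analogue is stronger: the
ACE Cholesky at ~1,000 pairs often absorbs familial covariance into C with
r_c at a boundary and pushes r̂_a toward +1 (median ≈ 0.79 against a
generating 0.53), while the AE submodel — the better fit by AIC in
essentially every replicate, exactly as in the emulated analysis — recovers
the generating genetic correlation (median ≈ 0.53).  This mirrors the
emulated study's own report that shared-environmental correlations were
unidentifiable (CIs spanning −1..+1) and that its data could not separate
genetic from shared-environmental sources of comorbidity.  Practical
guidance: read r_a from the AE fit whenever the ACE→AE Δχ² is ≈0.

## Problem sizes

Recovery checks use the study-scale 600 MZ + 440 DZ pairs with 25
replicates per fixture; generator-calibration checks use 2,000 individuals;
property checks (normalization, quadrature agreement, sandwich equality)
run on small fixed fixtures; the bootstrap-vs-profile comparison uses 400
bootstrap replicates on a binary AE fixture.  All randomness is seeded; the
acceptance script derives its replicate seeds from one command-line master
seed.

## Known limitations

- No dominance (ADE), sibling/parent extensions, multi-trait (>2) common
  factor models, or moderation/definition variables.
- AN is constructed at the phenotype stage but deliberately not fitted in
  twin models (too rare for stable concordant-pair counts), matching the
  emulated analysis.
- Absolute AICs against a saturated model are not reconstructed; AIC is
  reported only as differences between nested fits.
- The clustered-regression stage implements only the independence working
  model (point estimates are plain logistic ML; all correlation handling is
  in the sandwich variance).  An exchangeable working correlation would
  change point estimates slightly but not the robust inferences this
  pipeline reports, and was left out.
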