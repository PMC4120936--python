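# Methods

## Data model

Interview data are long-format CSVs: a participant roster (`id`, `sex`,
`age_years`, `migration_status`), a species registry keyed by short
codes, one ordered freelist per informant (`participant_id`, `rank`,
`species_code`), and use-reports (`participant_id`, `species_code`,
`use_category`, `use_type`). Use-type labels are free text from
transcriptions and are case-folded and whitespace-normalized before any
distinctness check; exact duplicates of a (participant, species,
category, use-type) tuple are treated as re-transcriptions and kept once.

Derived actor groups: age classes are half-open, lower-inclusive bins
[0, 20), [20, 40), [40, 60), [60, ∞) — boundary ages go to the upper
class, and ≥60 is closed below, matching the printed labels. The
migration factor splits non-migrants at 40 years (`no_young` / `no_old`)
and maps temporary/permanent migrants to `temp` / `perm`; in the
reference design every migrant is under 40, so the four levels partition
the roster. Favourite and "other important" freelist mentions are stored
as one concatenated ordered list per informant, because salience is
defined on a single ranked list.

## Indices

Per-informant salience is (L − r + 1)/L — "inverse rank over list
length". This is the only reading of inverse rank consistent with the
index's stated endpoint (salience 1 for a species listed first by
everyone); 1/(rL) would cap a first mention below 1 for any L > 1.
Composite Salience is the plain mean over informants; informants without
a freelist contribute 0 rather than being dropped, which keeps the
denominator at the roster size. Subgroup values use the subgroup size as
denominator, and the per-group "± " columns are standard deviations of
the per-informant values (the reference tables do not say sd or se; sd
is assumed).

CI uses, per species, the number of informants actually interviewed
about that species as denominator — inferred as "has at least one
use-report for it", since interview coverage is not recorded separately;
a config flag (`assume_all_asked`) substitutes the full roster. The
identity CI × #participants = #citations (participant-by-category
pairs) holds exactly before rounding and is enforced in tests.
Informants without a record for a species are excluded from its subgroup
CI denominators (not counted as zero-mention informants); this is a
choice, as the source material does not specify it.

## Group comparisons

ANOVA responses are per-informant values in [0, 1]: salience directly;
for CI the informant's number of mentioned categories divided by 9 —
the arcsine-square-root transform needs a [0, 1] argument and the
per-informant category count is the natural informant-level CI summand.
The classical between/within decomposition is computed directly (and is
checked against an independent sums-of-squares oracle to 1e-10); Tukey
contrasts use the studentized-range (Tukey–Kramer) form because the
migration groups are unbalanced (8/20/6/6 in the reference design).

The per-category two-group tests are 1-df pooled chi-square tests on the
2×2 mention table without continuity correction, which is the form the
reference results report; an exact two-sided binomial test (group 1's
count against group 2's observed proportion) is available behind
`exact=True`. The significance threshold is 0.05 throughout, with no
multiple-testing correction across species — matching the analysis
being reproduced; treat per-species significance accordingly.

## Count models

Response: distinct use-type counts (per species = informant totals; per
use-category = informant × species cells). Covariates: age in years
(continuous, uncentred — estimates are reported on the natural scale
and the IRLS fit is stable at this scale), sex, and a pooled migrant
indicator (temporary + permanent), with all two-way interactions in the
maximal model. Poisson GLMs are fitted by maximum likelihood
(statsmodels, log link). Overdispersion is assessed as residual deviance
/ residual df; above a threshold (default 1.5, configurable) the model
is refitted as quasi-Poisson: identical estimates, standard errors
scaled by √dispersion, t statistics on the residual df, and F-tests on
scaled deviance for term deletion. (The dispersion statistic is biased
somewhat below 1 for very small Poisson means; the default threshold is
deliberately above 1 so this bias cannot trigger spurious refits.)

Stepwise-backward simplification deletes, among terms not contained in a
retained interaction (marginality), the one with the largest deletion
p-value while that p exceeds α = 0.05; Poisson models use
likelihood-ratio chi-square tests, quasi models F-tests with the fuller
model's dispersion and residual df. Terms are held in a canonical order,
so the outcome does not depend on how the caller lists covariates; the
drop log records every deletion. Its per-term type-I rate is nominal:
on null data the final model is intercept-only at ≈ 0.95⁶ of
replicates, as expected from six droppable terms at 5% each.

## The crossed random-intercepts GLMM

Counts within a use-category are pseudo-replicated across informants and
species, so the model adds crossed random intercepts:
log μ_ij = x_ij′β + a_i + b_j, a_i ~ N(0, σ_p²), b_j ~ N(0, σ_s²).
The marginal likelihood is approximated by a Laplace approximation (one
quadrature point). Fitting proceeds in two stages: (1) Nelder-Mead over
the two log-sds, with (β, u) at the joint penalized mode found by
Newton iterations (tolerance 1e-8, at most 500 iterations, step
halving); (2) a polish of (log σ_p, log σ_s, β) against the *true*
Laplace objective with the random effects at their conditional mode,
since the joint-mode β profiles the penalized rather than the Laplace
objective. The Newton system is solved by eliminating the diagonal
informant block, leaving a dense solve only in the small species +
fixed-effects block, so a 200-informant × 14-species fit takes well
under a second. Fixed-effect covariances are conditional on the
variance estimates (the usual mixed-model practice). A fitted log-sd at
the lower bound (−6) is flagged as a boundary estimate, not an error;
with a single species the model reduces to one random intercept and the
species variance is reported as not estimable. Fits are ML, so
likelihood-ratio tests drive the same stepwise simplification as for
GLMs. The implementation reproduces `lme4::glmer` (Laplace) fixed
effects, variance components, and log-likelihood on test fixtures to
about three decimals.

## Synthetic data generator

The generator reproduces the reference study design: five women and five
men per age class (ages uniform within [16, 20), [20, 40), [40, 60),
[60, 80)); six temporary and six permanent migrants drawn from the
under-40 informants (8/20/6/6 migration-group split); 14 species; nine
use-categories.

Freelists follow a Plackett–Luce scheme — species drawn sequentially
without replacement with probability ∝ exp(utility) — the minimal
generative model in which a latent attractiveness is informative about
rank. List lengths are truncated Poisson (mean 5, minimum 1, capped at
the registry size), giving the 2–10 range typical of woody-plant
freelists. Default attractiveness is log(published Composite S + 0.02),
so the synthetic salience ordering tracks the reference community's.
Covariate effects on attractiveness (per-species age slope, migrant and
sex shifts) default to zero, because the reference survey reports group
differences in salience only as test outcomes, never as effect sizes;
power and recovery studies switch them on explicitly. A uniform shift
across all species would cancel in the softmax, so these effects are
per-species by construction.

Use-type counts are Poisson per informant × species × category with
log-mean = category intercept + age·slope + migrant deficit +
informant intercept + species intercept. Default coefficients are the
reference survey's fitted per-category values (intercepts −0.36 to
−2.88; age slopes +0.013/+0.014/+0.011 for medicine/other/tools;
migrant deficits −0.391/−0.377/−0.975 for construction/fodder/other;
zero elsewhere), with random-intercept sds 0.3 (informant) and 0.5
(species). A count of k appears as k distinct synthetic labels
("medicine type_001", …): the observed use-type vocabulary is emulated
in count, not content. All randomness flows through a single seeded
numpy PCG64 generator, so a fixed seed reproduces a dataset
byte-for-byte.

What synthetic data do *not* emulate: freelist preferences and use-type
counts are drawn independently, so the strong concordance between
Composite Salience and CI seen in real data (published rho = 0.81) is
absent by default; interview coverage is complete (every informant asked
about every species), whereas the reference per-species denominators
range 32–40; and use-type labels carry no semantics. Passing tests on
synthetic data therefore demonstrate calibration and recovery of the
statistical machinery under the design, not field realism of any single
dataset.

## Numerical and reporting choices

Index tables round to 6 decimals on disk and round-trip losslessly at
that precision. Significance stars follow the * / ** / *** convention at
0.05 / 0.01 / 0.001; model tables print `ns` for terms eliminated by the
stepwise procedure. Degenerate cases are first-class: all-zero count
responses are flagged rather than fitted (no finite intercept), a
zero-between/zero-within ANOVA is flagged degenerate, and per-species
model failures in the pipeline drivers are logged and skipped so one
pathological species cannot abort a 14-species run.

Test problem sizes were chosen so each Monte-Carlo suite pins its
property with comfortable margin at fixed seeds: 2000 replicates for the
stepwise type-I calibration, 200 for GLM effect recovery (n = 500),
100 for GLMM recovery (200 informants × 14 species), 100–300 for
dispersion and generator calibration checks.

## Known limitations

- The GLMM covariance of fixed effects ignores uncertainty in the
  variance components (as does lme4's default); p-values for fixed
  effects are Wald/LRT-based, with no small-sample (Kenward-Roger-type)
  correction.
- Quasi-Poisson F-tests use the fuller model's deviance-based
  dispersion; Pearson-based dispersion is not offered.
- Species-variance estimates from 14 species are intrinsically noisy
  (sampling CV ≈ 40%); interpret them as order-of-magnitude.
- No informant-consensus indices (e.g. FIC), no negative-binomial
  alternative, no multiple-testing correction across species.
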