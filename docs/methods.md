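# Methods

This note documents the statistical content of `emodyad`: the scoring
rules, the estimators, the synthetic-cohort generator, and the numerical
and design choices a maintainer or reviewer would want spelled out.

## Scoring daily-diary emotion data

**Items and scale.** Sixteen emotion adjectives per evening — 7 negative
(anxious, sad, angry, frustrated, disgusted, lonely, ashamed) and 9
positive (enthusiastic, happy, satisfied, confident, calm, like you
belong, close to others, proud, full of life) — each rated 0–4 ("none
of the time" … "all of the time").

**Composites.** The daily composite for a valence is the mean of that
day's *available* items; a person's mean emotion is the unweighted mean
of daily composites over their available days. Requiring complete item
batteries would discard usable days for no inferential gain, so partial
days contribute whatever they carry; a day with no rating of either
valence contributes nothing and does not count toward inclusion.

**Emodiversity.** For one person and valence, let `c_j` be the 0–4
ratings of emotion `j` summed across days and sort them non-decreasingly
(`c_(1) ≤ … ≤ c_(m)`). The score is one minus the classical Gini
inequality index:

    Gini = 1 − [ 2 Σ_j j·c_(j) / (m Σ_j c_(j)) − (m+1)/m ]

Properties (all property-tested): permutation and positive-scale
invariance; equal to `1 − Σ_{a,b}|c_a − c_b| / (2 m² c̄)` (the
mean-absolute-difference form); maximum 1 attained exactly at equal
totals; minimum `1/m` when all mass lies on a single emotion. Note the
analytic floor is `1/m`, not 0, even though the score is conventionally
described as ranging from 0 to 1; we implement the formula verbatim and
do not rescale. All-zero totals leave diversity undefined (NaN with a
logged reason) rather than silently 0 or 1.

Aggregating **summed intensities** rather than binary daily endorsements
is deliberate: the 0–4 anchors are frequency wordings, so the totals
carry the relative-abundance component of diversity (how much of one's
emotional life each emotion occupies) alongside richness (how many
emotions appear at all). Binarized endorsement counting is a coarser
alternative that discards the abundance information.

**Inclusion rules.** A dyad enters analysis only if both members have
diary data and both have at least `min_days` (default 6) days with ≥1
emotion rating — below that, emodiversity totals are too sparse to be
stable. The rules are applied symmetrically and jointly, so the retained
set does not depend on rule order; exclusion reasons (`no-partner-part2`,
`fewer-than-6-days`, `partner-insufficient`) are all recorded per dyad.

**Reliability.** Between-person reliability of the k-item, d-day person
mean uses a generalizability-theory decomposition. After removing fixed
item effects (item grand means), ratings are modelled as person +
person×item + residual. Method-of-moments on the unbalanced three-way
layout: the residual variance comes from within-cell (person×item)
variation across days; the person×item variance from between-item
variation of cell means within person, debiased by `σ²_e/d̃`; the person
variance from between-person variation of person means, debiased by
`σ²_pi/k + σ²_e/(k·d̃)`; with `d̃` the harmonic mean of person day counts
(so persons with few days do not dominate the debiasing terms) and
negative moment estimates truncated at 0. Reliability is

    R = (σ²_p + σ²_pi/k) / (σ²_p + σ²_pi/k + σ²_e/(k·d̃))

— the person×item term sits in the numerator because stable
idiosyncratic item profiles are reproducible person-level signal for a
fixed item set. The estimator is deterministic and dependency-free;
a multilevel (REML) decomposition would be an acceptable alternative and
differs only in finite-sample weighting. Cronbach's alpha (complete-case
variance ratio) covers the single-occasion symptom questionnaires.

## The actor–partner model and its estimation

Each of the four models (valence × symptom) regresses both members'
baseline symptom means on six dyad-level terms: adolescent mean emotion,
adolescent emodiversity, their product, and the caregiver counterparts.
Mean and diversity columns are grand-mean centered and products are
formed from centered factors (configurable off): this leaves main
effects interpretable at sample-average levels and decorrelates them
from the interaction; slopes are unaffected, and the no-centering
variant is one flag away for comparisons against software that centers
differently. With every path free the model is just identified: fit
indices are vacuous and complete-data ML equals per-equation least
squares, which the implementation exploits by solving the complete-data
case in closed form (OLS coefficients, ML residual cross-moment
`Σ̂ = EᵀE/n`).

**FIML.** With partially missing outcomes, each dyad contributes the
density of its observed outcomes only — the bivariate normal for
complete pairs, the univariate marginal otherwise (dyads missing both
outcomes are dropped as uninformative; predictors are complete by
construction after exclusions, and rows with undefined emodiversity are
dropped with a warning). The observed-data log-likelihood is maximized
by BFGS on an unconstrained parameterization — coefficients, log
residual SDs, atanh residual correlation — with analytic gradients and
OLS starting values. Convergence is judged on the average per-dyad
gradient (flagged below 1e-7, hard error above 1e-5) so the criterion is
sample-size invariant. Exogenous predictor correlations are reported as
sample correlations rather than estimated as free Gaussian parameters;
in a just-identified model with fixed regressors this changes no path
estimate.

**Robust (sandwich) inference.** At the optimum, per-dyad score vectors
are analytic; the bread `A` is the average negative Hessian obtained by
central differences of the analytic score (step 1e-6, scaled), and
`V = A⁻¹ B A⁻¹ / n` with `B` the average score outer product, times a
small-sample factor `n/(n−1)` (configurable). This is valid under
residual non-normality and, for the regression paths, under
heteroskedasticity; SEs of exact-ML variants differ only by a scaling
constant, so cross-software SE comparisons should allow a few percent.
Classical (inverse-information) covariance is kept alongside for
diagnostics. Standardized paths use `β = b·SD(x)/SD(y)` with sample SDs
of the realized columns (the product column's own SD for interactions)
treated as fixed in the delta rule; p-values are standard normal
(two-sided), with no small-sample df correction, matching common SEM
practice.

**Multigroup analysis** refits the model independently within strata
(default: adolescent gender), excluding and reporting strata below
`min_group_n = 10` — small enough groups yield unstable 17-parameter
fits. The design is centered once globally so group contrasts are on a
common scale.

**Conditional effects.** For a focal path with coefficient `b1` and its
product with a centered moderator `b3`, the effect at moderator value
`x` is `b1 + b3·x` with variance `V11 + x²V33 + 2xV13` from the robust
covariance; bands use the normal quantile at the requested level (95%
for tables, 99% for the exported curves). The default grid is moderator
mean ± 2 SD in 41 steps. Curves are computed on the unstandardized
scale, where the delta-method covariance is exact; standardized display
is a relabelling of axes.

## The synthetic cohort generator

The generator is a first-class module: it is the ground-truth instrument
for every estimator test. It emulates the targeted study design — 175
dyads, 14 scheduled days, 84%/88% adolescent/caregiver compliance
(missing completely at random), trait negative/positive affect levels
and spreads anchored to published descriptives of caregiver–adolescent
evening diaries (adolescent NA 0.90, caregiver NA 0.67, adolescent PA
2.04, caregiver PA 2.15 on the 0–4 scale).

Person-day ratings follow a latent-affect measurement model: daily
latent affect = trait + N(0, 0.5); item rating = latent × item
discrimination (N(1, 0.45), floored at 0.2) + stable person×item
affinity (N(0, 0.35)) + item noise (N(0, 0.4)), rounded and clamped to
0–4. Emodiversity is therefore *emergent*: discrimination spread and
the person×item affinity concentrate each person's reports on
idiosyncratic emotions. The affinity component is what gives realistic
Gini levels and between-person spread (emergent negative-valence Gini
≈ 0.73–0.75, SD ≈ 0.08; positive ≈ 0.86); without it, noise spreads
mass too evenly and diversity saturates. Round-and-clamp discretization
slightly compresses trait differences near the scale floor (realized
mean NA runs ~0.05–0.1 above the nominal trait mean), which we accept
as the price of bounded integer support.

Baseline symptoms are linear in the *realized* (post-missingness)
centered predictors with the configured actor/partner coefficients —
default actor mean-emotion effects 0.5 (adolescent) and 0.55
(caregiver), small actor diversity/interaction effects (0.1), null
partner effects, residual SDs ≈ 0.2–0.45 and partner residual
correlations 0.20–0.25 — plus correlated bivariate-normal residuals,
with 5% MCAR missingness per symptom. Outcomes are *not* clamped to the
0–3 instrument range: clamping would break the linearity that makes
truth exact, so Gaussian tails can occasionally graze the bounds; the
reader therefore warns rather than errors on out-of-bounds symptom
means by default (strict mode is available for real instrument data).
A test asserts that the truth record's realized predictors match the
scoring pipeline's recomputation to 1e-12, so generator and analysis
can never drift apart silently.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: temporal autocorrelation and
weekday/weekend structure in affect; ordinal item response behaviour
beyond round-and-clamp; informative (non-MCAR) missingness; selection
into the study; and any nonlinearity of the symptom–emotion relation.
Estimator calibration results transfer to real data only insofar as the
MCAR and linear-model assumptions hold there.

## Problem sizes and numerical checks

Validation sizes were chosen to pin each claim with comfortable
Monte-Carlo margins: least-squares equivalence at machine tolerance on
single fixtures; FIML bias under 20% MCAR averaged over 40 replicates
at n = 2000; robust-CI coverage and null rejection over 500 replicates
at the study's n = 175; heteroskedastic coverage over 500 replicates at
n = 300; residual-correlation recovery at n = 5000. All random tests
run under fixed seeds and fixed generator defaults.

Degenerate inputs are handled explicitly: all-zero emotion totals (NaN
diversity with reason), all-constant ratings (undefined reliability),
zero total-score variance (undefined alpha), zero-variance outcomes and
rank-deficient designs (errors naming the offending columns), groups
below minimum size (excluded and reported), and non-PD covariance
proposals during optimization (rejected via the unconstrained
parameterization, which cannot produce them).

## Known limitations

- The reliability decomposition is method-of-moments, not REML; printed
  reliabilities from multilevel software will differ slightly in
  unbalanced data.
- Sandwich SEs use one specific scaling (`n/(n−1)`); SEM packages use
  several variants, so SE comparisons across software carry a few
  percent of slack by construction.
- The APIM here is cross-sectional at the person level; day-level
  dynamics (lability, inertia, within-day diversity) are out of scope.
- Multigroup fits share the global centering but estimate all parameters
  freely per group; no equality-constraint tests across groups are
  provided.
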