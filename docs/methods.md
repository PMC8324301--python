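# Methods

This note documents the models implemented in `symbiofit`, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the numerical and design choices made where the design was genuinely open.

## Dose–response inference

Grouped mortality counts (deaths out of n tested per concentration) are
modeled as binomial with success probability g⁻¹(α + β·log10 d), where g
is the probit link by default (logit available; the two give LC50s within
a few percent for slopes in the 1–4 probit/decade range typical of Cry
toxin assays). Fitting is by iteratively reweighted least squares on the
working response, iterated to a relative deviance change below 1e-8 with
at most 50 iterations. A surviving larva below 5 mg body mass is scored
dead before grouping: growth that arrested at the neonate stage is treated
as toxicological death, and the 5 mg cut is strict (a 5.0 mg larva lives).

The LC50 is 10^(−α/β). Its standard error on the log10 scale comes from
the delta method applied to the coefficient covariance; when the Pearson
χ²/df of the fit exceeds 1 the covariance is inflated by that
heterogeneity factor, the standard practice in bioassay software for
over-dispersed dose groups. Confidence intervals use the normal quantile
on the log10 scale and are then exponentiated; Fieller-type intervals are
not implemented — at the group sizes this package targets (72
larvae/dose) the delta interval's coverage is 90–99%, which the test
suite verifies by simulation.

Abbott's correction is available when a dose-0 control group is present:
observed mortalities are rescaled by (p − c)/(1 − c) with c the pooled
control mortality, producing fractional pseudo-counts that the binomial
IRLS accepts.

The pooled model across arms is a binomial GLM with terms entering in the
fixed order strain, log10(dose), strain × log10(dose), infection status;
each term's χ² is its sequential deviance drop (type-I decomposition).
Sequential testing was chosen over marginal Wald tests because the
scientific question — does infection shift mortality after strain and
dose effects are absorbed? — is inherently ordered.

The across-strain regression of infected-arm LC50 on uninfected-arm LC50
tests whether the absolute benefit of infection grows with resistance
level: t = (slope − 1)/SE(slope) on n − 2 degrees of freedom. With n
strains the df is n − 2; published analyses of this design sometimes
report fewer df (robust variants drop points), so df is reported
explicitly rather than assumed.

## Life-table analysis

Thirteen fitness components are recorded per individual: survival from
1st to 5th instar, survival from 5th instar to pupation, larval duration,
pupal weight, female and male pupal durations, adult emergence, sex,
copulation, female and male adult longevities, fecundity, and egg hatch
rate. The net reproductive rate composes the subset that counts daughters:

    R0 = s(L1→L5) × s(L5→pupa) × emergence × copulation
         × fecundity × hatch × proportion female

each factor the cohort mean of its component. This is the minimal
multiplicative chain from a neonate female to a hatched daughter egg;
durations, weight and longevity describe *when* and *how large*, not *how
many*, and are deliberately excluded. Because the composition is a product
of means, the ordering of survival (applied to mothers or to daughters)
does not change the value.

Uncertainty is a nonparametric bootstrap over individuals (default 1000
resamples, seeded): individuals are the recorded unit and per-arm error
bars are wanted, so resampling replicates would discard most of the
information at three replicates per arm. Resamples that lose a
sex-specific component entirely (e.g. no females drawn) are discarded and
counted. Against a closed-form delta-method oracle in the
one-random-component case the bootstrap SE agrees within 15%.

Fitness cost is 1 − R0(focal)/R0(reference). The infection rescue effect
is a paired t-test across strains on raw R0 differences (log-ratio mode
available); the headline effect size is reported as the mean percent
change because that is the natural scale for "X% higher R0".

The plant-feeding growth assay is an ordinary least squares factorial of
day-9 larval weight on cotton variety × strain × infection (48 larvae × 3
repeats per cell by default). Main effects are tested sequentially; the
entire interaction block is tested with a single F comparing the additive
model against the full factorial, which is the direct formalization of
"do the effects combine additively?".

## RADR

The relative average development rate of an isofemale line is the mean
developmental-stage rating of its larvae on toxin diet divided by the
mean rating on control diet, scored after a fixed exposure (6 days in the
motivating assays). RADR is computed per line and lines are then averaged
— the line is the genetic unit, and pooling larvae would weight lines by
their survival. Larvae dead before scoring are excluded by default
(ratings are defined for scored survivors); the `zero` policy instead
counts each dead larva as a zero rating, which is the right choice when
toxin-diet mortality itself carries tolerance information. Both policies
are exposed because assay protocols differ on this point.

RADR comparisons across infection status and year use sequential-F
ordinary least squares on line-level values; with a single factor the
status F reduces exactly to the squared two-sample t.

## Symbiont spread

The recursion tracks the infected host frequency p through one generation:

1. selection: p\* = wp / (wp + 1 − p), infected hosts reproducing with
   relative fitness w;
2. vertical transmission with fidelity v: p_v = v·p\*;
3. horizontal acquisition by mass action with coefficient h:
   p′ = p_v + (1 − p_v)·h·p\*.

This is the simplest family that reduces to pure relative-fitness
selection at v = 1, h = 0 and still exposes both transmission routes a
vertically-and-horizontally transmitted symbiont uses. Defaults are
v = 1, h = 0, w = 1.38 (the ~38% net-reproductive-rate uplift measured
for infected hosts), p0 = 0.01 and a near-fixation threshold of 0.99;
the start frequency and threshold are reported in all outputs because
"near fixation" is a convention, not a measurement. Under pure selection
the odds of infection multiply by w each generation — logit(p) advances
by exactly ln w — so the time to threshold is
ceil(ln[odds(p₁)/odds(p₀)] / ln w): 29 generations for the defaults,
about seven years at four generations per year. With v < 1 fixation is
impossible and the recursion settles at the interior fixed point, which
simulation matches to 1e-6.

The Wright–Fisher companion draws each next frequency as
Binomial(N, p′)/N, adding drift at finite population size N; it is seeded
and reproducible, and its across-seed mean tracks the deterministic
trajectory within binomial noise.

Relative fitness is recovered from field prevalence by a binomial logit
GLM of positives on calendar year: under pure selection the yearly logit
slope is (generations per year) × ln w, so ŵ = exp(slope/g) with a
delta-method SE. The estimator is exact on noiseless series and recovers
w within 5% (median over seeds) at realistic sampling effort (200
insects/year over 10 years).

## Prevalence trends

Field prevalence models are binomial logit GLMs on grouped counts fitted
by the same IRLS core. Terms: calendar year (linear, optionally
quadratic), crop status (toxin vs conventional), years since the toxin
crop first reached 10% of planting in a province (inclusive threshold),
the planted proportion itself, crop-cover fractions and environmental
covariates, plus pairwise interactions. Calendar year is the reported
scale — intercepts in the hundreds are expected — but fitting uses a
centered-year parameterization for conditioning, with coefficients and
covariance mapped back exactly through the polynomial expansion. Grouped
and per-individual-expanded data give identical coefficients.

Model comparison is by likelihood ratio: χ² is the deviance difference,
df the parameter difference; the LRT is additive along nested chains and
calibrated (≈5% rejection at α = 0.05 under the null). Complete
separation raises an error instead of reporting meaningless standard
errors; an optional continuity correction (0.5 successes and failures per
group) handles degenerate tables. Quadratic-vs-linear year selection is
left to an explicit LRT at α = 0.05 rather than automated. Pseudo-R²
values for logistic fits are deliberately not reported: the common
definitions disagree and none corresponds to a printed "R²" without
knowing which was used.

## Synthetic data

The generators are pure functions of (design, seed) and emulate the
statistical structure of the four assay streams at the study's design
sizes: 72 larvae per concentration and six concentrations per bioassay
arm; 30 larvae × 3 replicates per life-table cohort; 24 neonates per diet
per isofemale line; ~100 insects per province-year prevalence sample.

Distributional choices are the simplest families matching each
component's support, since the assays record only means: Bernoulli for
survivals and rates, truncated normal (above zero) for durations and
weights, Poisson for fecundity, per-egg Bernoulli for hatching. Life-table
components are drawn independently per individual rather than
conditionally on earlier stages; this keeps every column's mean equal to
its design value so the R0 product has an exact oracle. Mortality in the
bioassay stream follows c + (1 − c)Φ(β(log10 d − m)), an Abbott-style
mixture so the control-correction path is exercisable. Ratings are
continuous truncated-normal scores clipped to [0, scale max] by default —
this preserves configured mean ratios exactly (a Bt mean of 3.1 over a
control mean of 5.0 yields RADR 0.62) — with an integer mode for
instar-count scales, where rounding shifts means by up to half a point.
Prevalence counts are binomial around a logistic calendar-year trend; the
preset trend (yearly logit slope ≈ 0.495 from ~45% in 2007 to ~99% in
2016) matches the pace of the motivating field system.

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: overdispersion beyond binomial/Poisson
(no clutch effects, no shared-plate correlation), spatial or migration
structure between provinces, seasonality and overwintering phenology,
assay batch effects, and any genetic architecture linking host resistance
loci to symbiont carriage. Parameter-recovery results here certify the
estimators, not the field biology.

## Numerical choices and degenerate inputs

- IRLS: relative deviance tolerance 1e-8, max 50 iterations; fitted
  probabilities clipped to [1e-10, 1 − 1e-10]; rank deficiency detected
  up front with the aliased columns named; separation (|logit| > 25)
  raises rather than returning divergent SEs.
- Dose–response preconditions: ≥ 3 positive-dose groups, non-identical
  doses, not all-dead/all-alive; violations raise with the reason.
- Closed-form generations-to-threshold guards the ceil() against float
  rounding at exact crossings and agrees with the iterated recursion on
  randomized draws.
- Bootstrap ties: a cohort of identical individuals gives SE exactly 0;
  single-line summary groups report SE 0 with a degenerate flag.
- Exact-fit regressions (r² = 1) report infinite F / zero SE explicitly
  rather than dividing by zero.

## Known limitations

- The bioassay CI is delta-method only; for very shallow slopes or tiny
  groups Fieller intervals would be more faithful.
- R0 composition assumes the component means are independent entries of a
  product; covariance between components (e.g. heavier pupae laying more
  eggs) widens the true uncertainty beyond the individual bootstrap.
- The spread model is panmictic and unstructured; fixation-time estimates
  in subdivided populations with migration between selected and
  unselected regions will differ.
- `fit_w_from_prevalence` attributes the entire logit trend to selection;
  any horizontal transmission inflates ŵ.
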