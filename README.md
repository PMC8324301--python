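# symbiofit

Quantitative analytics for a question in insect–microbe ecology: when a
mutualistic symbiont raises its host's tolerance to an insecticidal toxin,
how fast does it sweep through pest populations under toxin selection, and
how is that sweep detected in laboratory assays and field surveys?

The motivating system is the cotton bollworm (*Helicoverpa armigera*)
carrying a densovirus that enhances larval growth and Cry1Ac tolerance in
regions planted with Bt-cotton. `symbiofit` implements the full analysis
chain for this kind of study, for ecologists and resistance-monitoring
groups who need the pieces as tested, reusable code:

- **bioassay** — mortality scoring (survivors under 5 mg count as dead),
  maximum-likelihood probit/logit dose–response fits of grouped mortality
  on log10(dose), LC50 = 10^(−intercept/slope) with delta-method CIs
  (heterogeneity-inflated when Pearson χ²/df > 1), Abbott's control
  correction, resistance/tolerance ratios, a pooled
  strain × dose × infection binomial GLM with a sequential
  likelihood-ratio table, and the regression of infected on uninfected
  LC50s with a slope-vs-1 t-test.
- **lifetable** — the net reproductive rate
  R0 = s(L1→L5) · s(L5→pupa) · emergence · copulation · fecundity ·
  hatch · proportion female (daughters per parental female,
  N(t+1)/N(t)), bootstrap SEs over individuals, fitness cost
  1 − R0(focal)/R0(reference), a paired t-test for the infection rescue
  effect, and a factorial linear model for plant-feeding growth assays.
- **radr** — the relative average development rate per isofemale line
  (mean developmental rating on toxin diet over the mean on control diet),
  status/year comparisons, and annual population summaries.
- **spread** — symbiont frequency dynamics
  p′ = v·p\* + (1 − v·p\*)·h·p\* with p\* = wp/(wp + 1 − p): haploid
  selection with relative fitness w, vertical fidelity v, and mass-action
  horizontal transmission h. At v = 1, h = 0 the recursion advances
  logit(p) by exactly ln w per generation, giving
  ceil(ln[odds(p₁)/odds(p₀)]/ln w) generations to any threshold; a
  Wright–Fisher companion adds binomial drift, and w can be recovered from
  prevalence time series via the yearly logit slope divided by the number
  of generations per year.
- **trends** — binomial GLMs (IRLS, logit link) of field prevalence on
  calendar-year terms (linear and quadratic), crop status, years since the
  toxin crop reached 10% of planting, and environmental covariates, with
  likelihood-ratio tests and simple linear trend fits.
- **synthetic_data** — seeded generators for all four data streams with
  known ground truth, so every estimator is testable end to end without
  any external data.

## Worked example

Fit a resistant strain's dose–response arms, estimate the infection
tolerance ratio, compose bootstrap R0 across strains, and ask how fast the
symbiont spreads:

```python
from symbiofit import presets, spread, bioassay, synthetic_data as sd, lifetable as lt

neg, pos = presets.bioassay_arm_designs("LF240")
fneg = bioassay.fit_dose_response(sd.gen_bioassay(neg, seed=11))
fpos = bioassay.fit_dose_response(sd.gen_bioassay(pos, seed=12))
tol = bioassay.resistance_ratio(fpos, fneg)

pairs = []
for i, strain in enumerate(("LF", "LF5", "LF60", "LF240")):
    dn, dp = presets.lifetable_arm_designs(strain)
    rn = lt.bootstrap_r0(sd.gen_lifetable(dn, seed=10 * i + 1), n_boot=1000, seed=1)
    rp = lt.bootstrap_r0(sd.gen_lifetable(dp, seed=10 * i + 2), n_boot=1000, seed=2)
    pairs.append((strain, rn.r0, rp.r0))
cmp = lt.rescue_comparison(pairs)

spread.generations_to_threshold(0.01, 0.99, 1.38)
```

This prints (formatting elided):

```
LF240 uninfected LC50 = 86.1 ug/mL  (95% CI 59.2-125.2)
LF240 infected   LC50 = 156.4 ug/mL  (95% CI 124.6-196.5)
tolerance ratio = 1.82  (95% CI 1.17-2.82)
LF: R0- = 131 +/- 17,  R0+ = 184 +/- 26
LF5: R0- = 117 +/- 15,  R0+ = 128 +/- 17
LF60: R0- = 93 +/- 14,  R0+ = 147 +/- 18
LF240: R0- = 51 +/- 8,  R0+ = 78 +/- 11
mean uplift = 40.5%  (paired t = 3.462, df = 3, p = 0.0406)
generations to near fixation: 29
```

Reading it: the infected LF240 arm needs ~1.8× more toxin for the same
mortality (the CI excludes 1), infection lifts the net reproductive rate
in every strain (~40% on average here), and a fitness advantage of that
size (w = 1.38) carries the symbiont from 1% to 99% prevalence in 29
generations — about 7 years at four generations per year.

The same pipelines are scriptable from the shell:

```sh
symbiofit simulate --seed 7 --out data/
symbiofit bioassay --input data/bioassay.csv --link probit --out fits.csv
symbiofit lifetable --input data/lifetable.csv --boot 1000 --seed 17 --out r0.csv
symbiofit radr --input data/ratings.csv --out radr.csv
symbiofit spread --w 1.38 --p0 0.01 --threshold 0.99 --out traj.csv
symbiofit trends --input data/prevalence.csv --terms year --lrt rainfall_mm --out fit.json
```

Every run writes a metadata JSON (seed, version, parameters) so outputs
are reproducible from the metadata alone.

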