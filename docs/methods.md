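# Methods

This note documents the model implemented by `ssbstroke`: its structure,
the defaults and why they were chosen, what the synthetic inputs emulate,
and the numerical and design decisions a user should know before trusting
or changing the results.

## Model structure

The package compares two closed populations — a reference arm and an
intervention arm that differ only in stroke incidence — with a
proportional multi-state life table. The 2012-style adult population
(ages 15+) is split into 5-year age bands crossed with sex; each cohort is
aged by single years until death or age 100. Band-level rates apply
uniformly to the single years inside a band; as a cohort ages it picks up
the rates of the band it currently occupies, and ages beyond the last band
reuse the last band's rates (a logged warning).

### Demand stage

The effective price change is Δp/p = tax rate × pass-on rate. The default
demand response is linear at the margin, ΔQ = Q·ε·Δp/p. The iso-elastic
form Q·((1+Δp/p)^ε − 1) is available via `TaxScenario(iso_elastic=True)`;
at Δp/p = 0.2 and ε = −1.299 the two differ by about 19 %, so the choice
is material and both are tested. Elasticities are applied identically
across age, sex and income strata. Portion-size scenarios rescale baseline
volumes by `portion_ml / 330`; 330 ml is the reference serving, so the
base case is unchanged. No substitution to tea, coffee, sweetened milk or
food is modelled, and diet beverages carry zero energy density, so their
substitution response never changes energy intake.

### Energy to BMI

The equilibrium relation (94 kJ/day sustained intake change per kg of
equilibrium body weight, SD 2.96) converts ΔE to Δw, applied in full from
the first simulated year — no phase-in, consistent with near-full effects
appearing in year 1 of the published results the model family reports.
Δw is converted to BMI units with the stratum mean height (defaults
1.68 m male, 1.58 m female, configurable); source data for heights are
not part of the published inputs, so this is a documented assumption.

BMI is log-normal per stratum via method of moments. The intervention
shifts the mean additively on the natural scale (not the log scale) before
refitting — matching the "shift the distribution" framing — and the SD
moves with the mean through a linear SD–mean relation whose slope is
estimated by least squares from two synthetic survey waves (knob
`sd_mean_slope`, default 0.25). A secular BMI trend (sensitivity lever)
adds `trend × year` to the mean of *both* arms; because the RR curve is
convex, the same ΔBMI averts more disease at higher baseline BMI, which
reproduces the published pattern of gains growing with the trend.

### Potential impact fraction

RR(x) = r^((x − 21)/5) above a theoretical-minimum-risk BMI of 21 kg/m²,
1 below it. The functional form and threshold follow GBD-style practice;
the source study cites GBD relative risks without printing the curve, so
both are configurable (`RRSpec`). r attenuates toward 1 with age. E[RR] is
the integral of RR against the log-normal density over (0, 80); the upper
truncation is required because an exponential RR against a log-normal
tail diverges, and the density mass beyond BMI 80 is < 1e-7 for all
plausible parameters. Two integration paths exist:

- `mean_rr`: adaptive quadrature (scipy QUADPACK) with break points at the
  RR kink and the density bulk, relative tolerance 1e-10 — the reference
  implementation, also used by `compute_pif`;
- `mean_rr_batch`: fixed-node Gauss–Legendre on two panels, vectorised
  over strata and years — used by the pipeline and Monte Carlo for speed.
  Tests pin it to the adaptive path at 1e-8 relative.

The PIF applies to stroke incidence only, from year 1 onward; case
fatality and 28-day fatality are unchanged by the intervention. With a
nonzero BMI trend the PIF is computed per model year over the reporting
horizon and held constant beyond it; reported outcomes never depend on
years past the horizon, so this is exact for all outputs.

### Life table

Annual difference equations with rate→probability conversion
p = 1 − exp(−r):

```
new_cases    = S · (1 − exp(−i·(1 − PIF)))
acute_deaths = new_cases · d28          # never enter the prevalent pool
case_deaths  = C · (1 − exp(−f))
other deaths = proportional to post-transition S and C at 1 − exp(−m)
```

Other-cause mortality is applied to the *post-transition* state
occupancies rather than start-of-year counts so that person conservation
(in = out + deaths) holds exactly and nobody dies twice; this is the one
place the verbal description of such models is ambiguous, and the
spreadsheet-oracle test pins the chosen order. Stroke deaths = acute +
prevalent-case deaths; "mortality" outcomes and "deaths averted" are
stroke-specific (all-cause differences are also reported). Mid-year
(trapezoid) populations are used for life years, prevalence reporting and
costs. Closed cohorts: no entrants after baseline.

HALYs per year are `LY · (1 − pYLD_bg) − C_mid · 0.28`, where the
stroke contribution (baseline prevalence × disability weight) is removed
from the total background pYLD so intervention-driven prevalence changes
flow into HALYs; the pYLD sensitivity lever scales the background term
only, which is why it moves only the DALY column of the grid. DALYs
averted are reported as HALYs gained (intervention − reference).
Discounting at rate ρ divides year-t values by (1+ρ)^t (t 0-indexed) and
applies to HALYs and costs only, never to case or death counts. Costs per
prevalent case-year use the sector-weighted unit cost
`0.18·c_priv + 0.82·0.70·c_priv`.

The grid's "prevalence" column is the end-of-horizon difference in
prevalent cases (the per-year output also exposes prevalent person-years
summed over the horizon, which answers a different question).

## Uncertainty and sensitivity

Monte Carlo draws vary exactly: elasticities (normal, per-beverage SD),
consumption means (normal with survey SE, resampled until ≥ 0), the
94 kJ/day-per-kg factor (normal, SD 2.96, resampled until > 0) and
relative risks (log-normal on the log-RR scale). Draws are reproducible
per (seed, index) via independent seed sequences; more than 1000
rejections for one parameter raises a configuration error. Intervals are
empirical 2.5th/97.5th percentiles of horizon totals; the default 2000
draws keeps percentile noise small relative to interval width. The
deterministic grid has 27 rows — tax 10/20/30 %, discount 0–3 %, portion
200/250/330/500 ml, cost scale 80–120 %, pYLD 100/105/110 %, BMI trend
0–0.3, pass-on 80–100 %, and an own-price elasticity of −0.85 — with the
base case cached so repeated rows are computed once.

## Synthetic inputs

`synthetic_data` emulates the *structure* of the restricted sources, not
their joint distributions. Encoded features: SSB intake declining with age
with the population-weighted mean calibrated exactly to 184 ml/day;
mortality and stroke incidence rising ~exponentially with age (incidence
scaled so yearly incident strokes land near the hundreds-of-thousands
scale of the original cohort model); prevalence set to the quasi-steady
state implied by incidence, case fatality and mortality (hence always
< 1); 28-day fatality near one third; RR per 5 BMI units attenuating from
~1.4 to ~1.08 across age; female BMI above male; elasticity defaults from
the LMIC beverage-price meta-analysis (own SSB −1.299, juice +0.388, milk
+0.129, diet +0.423) with stand-in SDs. Every knob is a `SyntheticConfig`
field; the manifest records the seed and true generating parameters so
tests can check recovery (log-normal refit within 3 SE at n = 10,000,
SD–mean slope within 0.1).

What passing tests on synthetic data do **not** show: agreement with the
published absolute totals (those depend on the restricted consumption,
mortality, cost and supplementary elasticity/epidemiology tables), or
realism of the age–sex joint distribution. They do show that the
arithmetic, integration, accounting identities, orderings and interval
behaviour of the method are correct, and those properties are
data-independent.

## Numerical choices and degenerate inputs

- Rates must be finite and non-negative; annual rates above ~2/yr trigger
  validation warnings because the annual cycle becomes coarse.
- Negative state occupancies raise a numerical error rather than being
  clipped.
- Log-normal fitting requires strictly positive mean and SD; shifted
  distributions with non-positive mean or SD raise degenerate-input
  errors.
- Percentage reductions where the reference outcome is zero are reported
  as NaN (undefined), never as 0.
- Null scenarios (tax 0, pass-on 0, all elasticities 0) produce *bitwise*
  identical arms: the PIF evaluates to exactly 0.0 and both arms execute
  identical floating-point operations.
- The Monte Carlo driver caps cohort simulation at the reporting horizon
  (`sim_years`); every reported quantity is a function of the first
  horizon years of state, so this is output-equivalent to simulating to
  age 100 and is used only for speed. Test-suite problem sizes (reduced
  age ranges, 5-year horizons, 500-draw coverage studies) were likewise
  chosen as the smallest sizes at which the checked properties are
  non-trivial.

## Known limitations

- No direct (non-BMI) SSB→stroke pathway and no mediation through
  diabetes or hypertension; estimates are conservative in that respect.
- No obesity-paradox RR modification, no informal/indirect care costs, no
  cost offsets from other diseases in added life years, no tax
  administration costs, no revenue estimate.
- Equilibrium weight change is immediate; individual-level dynamic weight
  models (e.g. Hall) are out of scope.
- Elasticities are income-invariant and the demand response is linear by
  default.
- The synthetic bundle is a labelled stand-in; absolute outputs should
  not be quoted as estimates for any real population.
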