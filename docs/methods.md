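# Methods

## Scope and approach

`oshburden` estimates the societal economic burden of work injuries and
diseases with an incidence-based, bottom-up design: all cases newly
incident in the reference year (2015) are followed over their lifetime, the
costs they trigger are valued in reference-year euros, attributed to
stakeholders, and summed to the national level. This answers "what would
the country gain if this year's injuries and diseases had not happened",
not "what is spent on them this year" (a prevalence design would answer the
latter).

The unit of computation is the **case cohort**: cases homogeneous in kind
(injury/disease), condition group, lost-work-time severity band, age
bracket and sex. Cohort counts may be fractional (attributable-fraction
estimates are carried at full precision; rounding happens only in reports).

## Incidence

Registered non-fatal injury counts are adjusted for underreporting with a
benchmark country's fatal-to-non-fatal ratio: fatalities are reliably
registered, so `fatal / benchmark_ratio` is a floor for the true non-fatal
count and the adjustment is `max(registered, fatal / benchmark_ratio)`.
The adjustment only inflates — a register already above the floor is
trusted. Work-related disease counts for condition groups with reliable
population data (cancers, musculoskeletal, respiratory, circulatory) are
`population incidence × attributable fraction`; other groups use register
counts. Totals are spread over severity bands by largest-remainder
rounding (ties broken by band order), which conserves totals exactly.

Severity bands mirror European reporting conventions — injuries 0–3 /
4–14 / 15–90 / 91–180 / 181–365 days lost, never-return, fatal; diseases
< 3 / 4–30 / 31–90 / > 90, never-return, fatal. Expected lost days per band
is the arithmetic midpoint (the sources publish bands, not means); the
open-ended "> 90" disease band is bounded at 365 for the midpoint. Cases
with more than six months of lost time are treated as permanently impaired:
for injuries that is the 181–365 and never-return bands; the disease bands
have no six-month edge, so only never-return is permanent and "> 90" is
treated as (long) temporary. Cohort ages are taken at the bracket
midpoint. An auxiliary `no_lost_days` injury band exists solely for the
scenario that adds injuries without any workday lost (they carry only the
nominal healthcare cost).

## Costing rules

**Direct.** Injuries with ≤ 3 days lost cost a nominal €100 per case (not
price-adjusted). All other cases cost
`unit_cost × price_adjustment_ratio × episode_years`, the unit cost being a
source country's tariff transferred via a hospital-services price ratio.
Episodes are capped at 1 year for injuries and short-episode disease
groups (hearing, infectious, skin, …) and run 1–2 years for chronic groups
(cardiovascular, respiratory, musculoskeletal, mental health, cancer);
the default for the latter is 1.5 years, the midpoint of the stated range.
Out-of-pocket and healthcare administration are fractions of the formal
cost. Informal caregiving is 1 h per lost day at the caregiving-services
wage, capped at 183 days; fatalities receive care only for days survived
(default 0).

**Indirect.** Human-capital valuation of lost market output:

- fractional-day cases (< 1 expected lost day): no productivity loss;
- temporary (≥ 1 day, < 6 months): `daily earnings × lost workdays`, with
  daily earnings = annual / 230 paid working days;
- permanent: 35 % of annual earnings from incidence to retirement age 65;
- fatal: 100 % from death (mid-incidence-year) to retirement.

All streams carry the country fringe-benefit uplift, 1 %/yr productivity
growth for calendar years beyond 2017, and discounting to 2015. The
discount rate is deliberately a single explicit knob (default 3 %/yr,
standard cost-of-illness practice); the published framework states only
that values are discounted to 2015 without printing the rate, and none of
the reproduced identities depend on it. The present-value engine walks
year offsets k = 0, 1, … (k = 0 being 2015), looks earnings up by attained
age in the bracket table (clamping above the last bracket), and weights a
fractional final year by its fraction. It is verified against an
independently coded year-by-year summation at 1e-9 relative tolerance.

Employer adjustment: absences of ≥ 4 days cost 0.5 managerial days plus
2.5 clerical hours; a fatality costs six months of the worker's gross
earnings. Home production: lost hours per day × lost days at the
domestic-services wage for temporary cases; for permanent and fatal cases
the stream runs over remaining conditional life expectancy, discounted and
grown like earnings (home production is a wage-valued stream, so it is
treated symmetrically). Presenteeism applies a condition-group output-loss
ratio over a 30-working-day window valued at daily earnings — after return
for injuries, both before and after the absence for diseases; excluded for
fatalities, for never-return cases, and for cases without a full lost day.
Insurance administration is a fraction of the earnings loss (10.1–12.2 %
by country).

**Intangible.** QALY losses only for cases with ≥ 3 expected lost days.
Temporary: `multiplier × lost days / 365`; permanent: multiplier × remaining
conditional life expectancy at the cohort age; fatal: one full QALY per
expected remaining life year. Life expectancy is interpolated on an age
grid (`AgeCurve`), which makes fatal losses strictly decreasing in age.
QALY streams are undiscounted by default (monetary values are discounted;
quality-of-life years are not — a `discount_qalys` flag exists). The QALY
value is stored as £30,000 with a fixed 1.37 €/£ conversion (€41,100):
storing GBP makes the revaluation scenarios at £20,000/£45,000 exact
ratios 2/3 and 1.5, which is what the published scenario table's two-decimal
change percentages are consistent with.

The default severity multipliers (temporary minor 0.1, temporary serious
0.3 — split at 30 expected lost days — permanent 0.4), the out-of-pocket
share (15 %), healthcare administration (4 %), presenteeism ratio (0.25)
and window (30 working days each side) are **placeholders**: the source
framework takes them from unpublished supplementary tables. They are
flagged in the shipped configuration and are plain JSON knobs.

## Stakeholder attribution and aggregation

Every euro of societal cost is attributed to exactly one stakeholder:
workers/families bear out-of-pocket, caregiving, home production, QALY
losses and the non-replaced share of earnings losses; employers bear
adjustment and presenteeism; the system/public sector bears formal
healthcare, both administration items, and the replaced share of earnings
losses. Wage replacement (default rate 0.8, midpoint of the 70–90 %
scenario range) is recorded as a transfer: it determines who bears the
earnings loss but never adds to the societal total, so stakeholder totals
always sum to the societal total (checked to 1 part in 10⁶, a violation is
an internal error). Comparison metrics: % of GDP, cost per case
(total / cases), cost per employed person. Report tables round to the
printed conventions (nearest M€ for totals, nearest € for per-case
figures, whole-percent shares, one-decimal %GDP) while keeping raw euro
columns for exact round-trips.

## Sensitivity engine

One-way scenarios re-run the entire pipeline at a parameter's lower and
upper bound and report %GDP plus the percentage change in total cost
(equal to the %GDP change at fixed GDP), to two decimals with
round-half-even. Supported parameters: disease-incidence scale
(compensated-only lower bound), injury underreporting scale (applied to
non-fatal injuries with ≥ 4 days lost), a no-workday-lost injury add-on,
the QALY value (GBP), a healthcare unit-cost scale (±80 %; caregiving is
wage-priced and deliberately unaffected), the permanent earnings-loss
fraction (33–38 %), caregiving caps per kind (183–550 days), and the
replacement rate (distributional only — the total is invariant). QALY
revaluation additionally has a closed form,
`change % = (ratio − 1) × intangible/total × 100`, because monetization is
a pure multiplier; tests verify the full pipeline and the closed form
agree, and the closed form lets the scenario be evaluated from published
category totals alone.

Known divergence: the published "injuries without workday lost" scenario
reports changes (e.g. +0.26 % for the smallest country) larger than the
stated €100-per-case rule can produce (≈ +0.16 % there). The rule is
implemented as stated and the discrepancy left visible rather than
reverse-engineered.

## Synthetic data

The generator emulates the *structure* the costing model consumes, not
condition-specific epidemiology: no latency, no age-specific hazards, no
industry mix. Counts are one multinomial draw per kind over the full
condition × band × age × sex grid from a single `numpy` generator seeded
with one integer (injuries drawn first, then diseases), so requested totals
are conserved exactly and bundles are reproducible across platforms.

Defaults are Finland-like, the smallest study country: 63,407 non-fatal
injuries with fatal rate 35/63,407, 68,423 diseases with 628 expected
fatalities, 2.44 M employed, GDP €86,000 per worker, fringe 22 %, insurance
administration 10.1 %. Severity distributions are register-like — most
injuries under 15 lost days, permanent impairment rare (2 % of injuries,
2 % of diseases never return); earnings follow a hump-shaped age curve
(base €38,000, peak ratio 1.10) with a 16 % sex gap; healthcare unit costs
range from €800 (skin) to €15,000 (cancer) per episode-year. Under these
defaults the synthetic burden lands near 3.6 % of GDP with
indirect > intangible > direct — inside the range of published national
estimates, which is all passing tests establish about real data: the
arithmetic is right under realistic magnitudes, not that any country's
true burden is reproduced.

Known-answer bundles restrict the spec to a single temporary injury band
with flat earnings and zero out every component except the absence earnings
loss, making the per-case cost exactly
`daily wage × lost days × (1 + fringe)`; the generator returns the
analytic summary alongside the bundle for parameter-recovery tests.

## Numerical choices and degenerate inputs

- Fractional cases and fractional horizon years are carried in full
  precision; the PV engine weights the final partial year.
- Largest-remainder ties break by band order (deterministic).
- Probability vectors must sum to 1 within 1e-9; all-zero vectors are
  rejected.
- Zero GDP, zero cases or zero employment make the respective ratio a hard
  error, not a NaN.
- Earnings lookups at incidence are strict (an uncovered age bracket names
  the offending stratum); lookups while ageing a cohort clamp to the
  nearest bracket.
- Report percentages use round-half-even at the stated precision.

## Limitations

- Stakeholder attribution uses a fixed allocation matrix plus the
  replacement rate; the published study's country-specific wage-loss
  split across stakeholders is not public, so employer shares here are
  smaller than published ones (sick-pay is attributed to the system).
- Friction-cost valuation, labour-market replacement dynamics, probabilistic
  sensitivity analysis and cross-country currency/inflation adjustment are
  out of scope.
- Placeholder parameters (QALY multipliers, presenteeism ratios,
  out-of-pocket and admin shares, episode midpoints) shift national
  magnitudes; conclusions that depend on them should re-run the sensitivity
  engine with country-specific values.
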