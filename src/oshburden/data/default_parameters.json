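{
  "_provenance": {
    "reference_year": "baseline framework: incident cases from calendar year 2015, all values in 2015 euros",
    "discount_rate": "not fixed by the framework's published description; 3%/year is standard cost-of-illness practice and is an explicit knob",
    "productivity_growth": "1% annual earnings growth applied beyond 2017",
    "growth_from_year": "first calendar year that receives the growth factor",
    "retirement_age": "standard retirement age 65",
    "impairment_output_loss": "permanently impaired cases lose 35% of output until retirement; sensitivity range 33-38%",
    "caregiving_hours_per_day": "one hour of informal care per lost day",
    "caregiving_cap_days": "no informal caregiving beyond six months (183 days); sensitivity upper bound 550 days",
    "fatal_caregiving_days": "fatalities receive care only for days survived; default 0",
    "qaly_value_gbp": "QALY valued at GBP 30,000 (EUR 41,100 at the fixed conversion); scenario bounds GBP 20,000 / 45,000",
    "gbp_to_eur": "fixed 1.37 EUR/GBP conversion for the QALY value",
    "qaly_min_lost_days": "quality-of-life losses counted only for cases with three or more days lost",
    "discount_qalys": "QALY streams undiscounted by default; monetary values are discounted, QALYs are not",
    "minor_injury_healthcare_cost": "nominal EUR 100 per injury case with three or fewer days lost; not price-adjusted",
    "qaly_multiplier": "PLACEHOLDER severity multipliers (fraction of a full QALY per year); the source study's multiplier table is not published - replace with national values when available",
    "presenteeism_ratio_default": "PLACEHOLDER output-loss ratio while working injured/ill; the source ratio table is not published",
    "presenteeism_window_days": "working-day window on each side of the absence over which presenteeism applies (30 working days, package default)",
    "treatment_episode_years": "1.5 years = midpoint of the 1-to-2-year episode for chronic condition groups; all other groups and injuries capped at 1 year",
    "working_days_per_year": "230 paid working days per year for day/year conversions"
  },
  "reference_year": 2015,
  "discount_rate": 0.03,
  "productivity_growth": 0.01,
  "growth_from_year": 2018,
  "retirement_age": 65.0,
  "impairment_output_loss": 0.35,
  "caregiving_hours_per_day": 1.0,
  "caregiving_cap_days": {"injury": 183.0, "disease": 183.0},
  "fatal_caregiving_days": 0.0,
  "qaly_value_gbp": 30000.0,
  "gbp_to_eur": 1.37,
  "qaly_min_lost_days": 3.0,
  "discount_qalys": false,
  "minor_injury_healthcare_cost": 100.0,
  "qaly_multiplier": {
    "temporary_minor": 0.1,
    "temporary_serious": 0.3,
    "permanent": 0.4
  },
  "presenteeism_ratio": {},
  "presenteeism_ratio_default": 0.25,
  "presenteeism_window_days": 30.0,
  "treatment_episode_years": {
    "injury": 1.0,
    "cardiovascular": 1.5,
    "respiratory": 1.5,
    "musculoskeletal": 1.5,
    "mental_health": 1.5,
    "cancer": 1.5,
    "hearing": 1.0,
    "skin": 1.0,
    "infectious": 1.0
  },
  "treatment_episode_years_default": 1.0,
  "working_days_per_year": 230.0
}
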