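# One-way sensitivity scenario library (Finland-like default bounds).
# Each entry feeds oshburden.sensitivity.ScenarioSpec; bounds for other
# countries substitute their own values via the CLI or API.
scenarios:
  # Lower bound: compensated disease cases only (share of the baseline
  # compensated-plus-attributable-fraction count); upper bound: baseline.
  - name: disease_incidence
    parameter: disease_incidence_scale
    low: 0.0262
    high: 1.0
    scope: diseases
  # Non-fatal injury underreporting adjustment ratio applied to cases with
  # four or more days lost.
  - name: injury_underreporting
    parameter: injury_incidence_scale
    low: 1.1
    high: 1.2
    scope: injuries
  # Add injuries without any workday lost (nominal healthcare cost only).
  - name: injuries_no_workday_lost
    parameter: minor_injury_addon_cases
    low: 0
    high: 97933
    scope: injuries
  # Willingness-to-pay per QALY, in GBP (baseline 30,000).
  - name: qaly_value
    parameter: qaly_value_gbp
    low: 20000
    high: 45000
  # +/- 80% of baseline healthcare treatment costs.
  - name: healthcare_costs
    parameter: healthcare_cost_scale
    low: 0.2
    high: 1.8
  # Earnings-loss fraction for permanently disabled cases.
  - name: permanent_earnings_loss
    parameter: impairment_output_loss
    low: 0.33
    high: 0.38
  # Informal caregiving cap for diseases with permanent disability (days).
  - name: caregiving_time_diseases
    parameter: caregiving_cap_days
    low: 183
    high: 550
    scope: diseases
  # Informal caregiving cap for injuries with permanent disability (days).
  - name: caregiving_time_injuries
    parameter: caregiving_cap_days
    low: 183
    high: 550
    scope: injuries
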