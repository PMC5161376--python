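# Default unit costs and macroeconomic parameters (EUR, Polish public payer).
# Every value can be overridden by a user-supplied YAML with the same schema.

paid_work_hour: 8.34          # EUR per hour of productivity loss at paid work
care_hour: 5.27               # EUR per hour of unpaid work / informal care
monthly_working_hours: 168.0
weeks_per_month: 4.345
days_per_month: 30.44
pln_per_eur: 4.2624
gdp_per_capita_annual: 10900.0
labour_elasticity: 0.65
default_body_weight_kg: 64.71
biologic_diagnostics_monthly: 54.90

# Macro inputs from which paid_work_hour is derived (GDP in EUR, employed
# persons, maximum annual working hours).
macro:
  gdp_annual_eur: 420164450000.0
  employed_persons: 16234000
  max_annual_hours: 2016

direct_costs:
  consultation_specialist: 7.57
  one_day_hospitalisation: 109.80
  medical_hospitalisation: 975.98
  surgical_hospitalisation: 1553.16

# Per-dose drug prices with dosing metadata.  Oral drugs are costed as one
# defined daily dose per day of the month; biologics as the cost of a
# 12-month course at recommended dosing divided by 12, with weight-based
# consumption where the schedule is per-kg.
drugs:
  sulfasalazine:      {unit_cost: 0.53, kind: oral}
  mesalazine:         {unit_cost: 0.53, kind: oral}
  prednisone:         {unit_cost: 0.24, kind: oral}
  budesonide:         {unit_cost: 0.03, kind: oral}
  azathioprine:       {unit_cost: 0.37, kind: oral}
  mercaptopurine:     {unit_cost: 0.31, kind: oral, unit_mg: 80.89, mg_per_kg_per_day: 1.25}
  methotrexate:       {unit_cost: 0.77, kind: oral}
  adalimumab:         {unit_cost: 967.01, kind: biologic, unit_mg: 80, annual_mg: 1240}
  infliximab:         {unit_cost: 298.23, kind: biologic, unit_mg: 100, annual_mg_per_kg: 40}

# Representative drug used to cost each class-level treatment flag.
flag_to_drug:
  aminosalicylate: mesalazine
  immunosuppressant: azathioprine
  glucocorticoid: prednisone
  biologic_adalimumab: adalimumab
  biologic_infliximab: infliximab
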