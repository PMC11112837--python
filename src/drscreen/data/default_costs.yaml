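# Baseline cost-model configuration: conventional ophthalmologist screening
# vs automated AI-based screening, USD, one visit per patient.
strategies:
  manual:
    screening_cost: 164.0          # DRG weight, fundus photography incl. screening
    transport_cost_round_trip: 73.0
    patient_time_hours: 1.5        # travel + time at the screening facility
    time_cost_per_hour: 24.0
    visits: 1
    transport_multiplier: 1.0
  ai:
    screening_cost: 33.0           # US government-program reimbursement, 2021
    transport_cost_round_trip: 73.0
    patient_time_hours: 1.0
    time_cost_per_hour: 24.0
    visits: 1
    transport_multiplier: 1.0
n_patients: 33
fraction_a: 0.5
nok_per_usd: 9.89
threshold: any                     # any | referable
ci_level: 0.95
weights: linear                    # identity | linear | quadratic
sweeps:
  - {strategy: ai, parameter: screening_cost, min: 33.0, max: 164.0, steps: 12}
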