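states:
- name: healthy
  utility: 1.0
  annual_state_cost_by_strategy: {}
  is_death: false
  event_cost: 0.0
- name: mild
  utility: 0.883
  annual_state_cost_by_strategy: {}
  is_death: false
  event_cost: 0.0
- name: moderate
  utility: 0.787
  annual_state_cost_by_strategy:
    DM: 223.53
    FDCT: 338.82
  is_death: false
  event_cost: 0.0
- name: severe
  utility: 0.382
  annual_state_cost_by_strategy:
    DM: 223.53
    FDCT: 338.82
  is_death: false
  event_cost: 0.0
- name: aur
  utility: 0.23700000000000002
  annual_state_cost_by_strategy: {}
  is_death: false
  event_cost: 29.41
- name: turp
  utility: 0.833
  annual_state_cost_by_strategy: {}
  is_death: false
  event_cost: 484.97
- name: death
  utility: 0.0
  annual_state_cost_by_strategy: {}
  is_death: true
  event_cost: 0.0
strategies:
- DM
- FDCT
transitions:
- strategy: DM
  from_state: healthy
  to_state: mild
  annual_probability: 0.29
- strategy: FDCT
  from_state: healthy
  to_state: mild
  annual_probability: 0.29
- strategy: DM
  from_state: mild
  to_state: moderate
  annual_probability: 0.29
- strategy: FDCT
  from_state: mild
  to_state: moderate
  annual_probability: 0.29
- strategy: DM
  from_state: moderate
  to_state: severe
  annual_probability: 0.16
- strategy: FDCT
  from_state: moderate
  to_state: severe
  annual_probability: 0.058
- strategy: DM
  from_state: moderate
  to_state: aur
  annual_probability: 0.13
- strategy: FDCT
  from_state: moderate
  to_state: aur
  annual_probability: 0.04
- strategy: DM
  from_state: severe
  to_state: aur
  annual_probability: 0.13
- strategy: FDCT
  from_state: severe
  to_state: aur
  annual_probability: 0.04
- strategy: DM
  from_state: moderate
  to_state: turp
  annual_probability: 0.16
- strategy: FDCT
  from_state: moderate
  to_state: turp
  annual_probability: 0.056
- strategy: DM
  from_state: severe
  to_state: turp
  annual_probability: 0.16
- strategy: FDCT
  from_state: severe
  to_state: turp
  annual_probability: 0.056
- strategy: DM
  from_state: turp
  to_state: turp
  annual_probability: 0.48
- strategy: FDCT
  from_state: turp
  to_state: turp
  annual_probability: 0.48
- strategy: DM
  from_state: severe
  to_state: moderate
  annual_probability: 0.46
- strategy: FDCT
  from_state: severe
  to_state: moderate
  annual_probability: 0.49
- strategy: DM
  from_state: moderate
  to_state: mild
  annual_probability: 0.46
- strategy: FDCT
  from_state: moderate
  to_state: mild
  annual_probability: 0.49
- strategy: DM
  from_state: aur
  to_state: severe
  annual_probability: 0.987
- strategy: FDCT
  from_state: aur
  to_state: severe
  annual_probability: 0.987
- strategy: DM
  from_state: healthy
  to_state: death
  annual_probability: 0.013
- strategy: FDCT
  from_state: healthy
  to_state: death
  annual_probability: 0.013
- strategy: DM
  from_state: mild
  to_state: death
  annual_probability: 0.013
- strategy: FDCT
  from_state: mild
  to_state: death
  annual_probability: 0.013
- strategy: DM
  from_state: moderate
  to_state: death
  annual_probability: 0.013
- strategy: FDCT
  from_state: moderate
  to_state: death
  annual_probability: 0.013
- strategy: DM
  from_state: severe
  to_state: death
  annual_probability: 0.013
- strategy: FDCT
  from_state: severe
  to_state: death
  annual_probability: 0.013
- strategy: DM
  from_state: aur
  to_state: death
  annual_probability: 0.013
- strategy: FDCT
  from_state: aur
  to_state: death
  annual_probability: 0.013
- strategy: DM
  from_state: turp
  to_state: death
  annual_probability: 0.013
- strategy: FDCT
  from_state: turp
  to_state: death
  annual_probability: 0.013
discount:
  annual_rate: 0.06
  convention: first-cycle-undiscounted
cohort:
  cohort_size: 2862363.0
  initial_distribution:
    mild: 1.0
  horizon_cycles: 10
  cycle_length_years: 1.0
wtp_threshold: 2450.0
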