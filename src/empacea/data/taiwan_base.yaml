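# Taiwan base-case inputs: monthly transition probabilities per arm,
# annual-scale utilities, monthly/one-off costs in 2020 US$.
schema: empacea-setting/1
label: Taiwan
wtp_1x: 25000
wtp_3x: 75000
arms:
  - name: empagliflozin
    p_hhf: {mean: 0.008811915, se: 0.002165244}
    p_cvd: {mean: 0.006589325, se: 0.00187447}
    p_ncd: {mean: 0.002113141, se: 0.001063894}
    drug_cost: {mean: 35, se: 17.5}
  - name: standard
    p_hhf: {mean: 0.012566527, se: 0.002578038}
    p_cvd: {mean: 0.007131185, se: 0.001947398}
    p_ncd: {mean: 0.002177683, se: 0.001078827}
    drug_cost: 0
econ:
  u_stable: {mean: 0.770, se: 0.016}
  u_age_decrement: {mean: -0.0016, se: 0.0001}
  u_hhf_decrement: {mean: -0.321, se: 0.02}
  cost_stable: {mean: 450, se: 225}
  cost_hhf: {mean: 2887, se: 1443.5}
  cost_pre_cvd: {mean: 3430, se: 1715}
  cost_pre_ncd: {mean: 3390, se: 1695}
  discount_rate_annual: 0.03
settings:
  start_age: 67
  horizon_cycles: 180
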