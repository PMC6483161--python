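# Modeled scan: rare (2%) vs common (20%) condition across realistic and
# exceptional score strengths, uniform and differential effectiveness.
name: rare_vs_common
columns:
  - label: rare_reasonable_rr4.7_top5
    prevalence: 0.02
    target: 0.05
    relative_risk: 4.7
    effectiveness: 0.90
  - label: rare_reasonable_rr3.0_top10
    prevalence: 0.02
    target: 0.10
    relative_risk: 3.0
    effectiveness: 0.90
  - label: rare_reasonable_rr2.4_top15
    prevalence: 0.02
    target: 0.15
    relative_risk: 2.4
    effectiveness: 0.90
  - label: rare_reasonable_rr2.0_top20
    prevalence: 0.02
    target: 0.20
    relative_risk: 2.0
    effectiveness: 0.90
  - label: rare_exceptional_rr10_top5
    prevalence: 0.02
    target: 0.05
    relative_risk: 10.0
    effectiveness: 0.90
  - label: rare_exceptional_rr9.0_top10
    prevalence: 0.02
    target: 0.10
    relative_risk: 9.0
    effectiveness: 0.90
  - label: rare_exceptional_rr5.6_top15
    prevalence: 0.02
    target: 0.15
    relative_risk: 5.6
    effectiveness: 0.90
  - label: rare_exceptional_rr4.0_top20
    prevalence: 0.02
    target: 0.20
    relative_risk: 4.0
    effectiveness: 0.90
  - label: common_predictive_rr4.7_top5
    prevalence: 0.20
    target: 0.05
    relative_risk: 4.7
    effectiveness: 0.90
  - label: common_predictive_rr3.0_top10
    prevalence: 0.20
    target: 0.10
    relative_risk: 3.0
    effectiveness: 0.90
  - label: common_predictive_rr2.4_top15
    prevalence: 0.20
    target: 0.15
    relative_risk: 2.4
    effectiveness: 0.90
  - label: common_predictive_rr2.0_top20
    prevalence: 0.20
    target: 0.20
    relative_risk: 2.0
    effectiveness: 0.90
  - label: less_effective_rr4.7_top5_e50
    prevalence: 0.20
    target: 0.05
    relative_risk: 4.7
    effectiveness: 0.50
  - label: less_effective_rr4.0_top10_e50
    prevalence: 0.20
    target: 0.10
    relative_risk: 4.0
    effectiveness: 0.50
  - label: less_effective_rr4.7_top5_e75_25
    prevalence: 0.20
    target: 0.05
    relative_risk: 4.7
    effect_target: 0.75
    effect_remainder: 0.25
  - label: less_effective_rr3.0_top10_e75_25
    prevalence: 0.20
    target: 0.10
    relative_risk: 3.0
    effect_target: 0.75
    effect_remainder: 0.25
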