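# Observed-prevalence scenarios: opioid use disorder, cardiovascular events
# under intensive blood-pressure therapy (annual rate), and osteoporotic
# bone fracture (lifetime risk), with projected score strengths.
name: observed_conditions
columns:
  - label: opioid_rr6_top1
    prevalence: 0.05
    target: 0.01
    relative_risk: 6.0
    effectiveness: 0.80
  - label: opioid_rr8.7_top5
    prevalence: 0.08
    target: 0.05
    relative_risk: 8.7
    effectiveness: 0.80
  - label: opioid_rr2_top33
    prevalence: 0.08
    target: 0.33
    relative_risk: 2.0
    effectiveness: 0.50
  - label: cad_rr3.3_top5
    prevalence: 0.022
    target: 0.05
    relative_risk: 3.3
    effectiveness: 0.25
  - label: cad_rr2.2_top20
    prevalence: 0.12
    target: 0.20
    relative_risk: 2.2
    effectiveness: 0.25
  - label: cad_rr1.6_top50
    prevalence: 0.12
    target: 0.50
    relative_risk: 1.6
    effectiveness: 0.25
  - label: cad_rr1.2_top80
    prevalence: 0.12
    target: 0.80
    relative_risk: 1.2
    effectiveness: 0.25
  - label: fracture_rr3_top8
    prevalence: 0.16
    target: 0.08
    relative_risk: 3.0
    effectiveness: 0.60
  - label: fracture_rr5_top10
    prevalence: 0.16
    target: 0.10
    relative_risk: 5.0
    effectiveness: 0.60
  - label: fracture_rr2.3_top50
    prevalence: 0.16
    target: 0.50
    relative_risk: 2.3
    effectiveness: 0.60
  - label: fracture_rr1.3_top80
    prevalence: 0.16
    target: 0.80
    relative_risk: 1.3
    effectiveness: 0.60
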