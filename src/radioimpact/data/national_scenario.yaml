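# National scale-up scenario for Burkina Faso (2012-2014).
#
# Printed inputs: national u5mr (103.3 / 97.7 / 92.8 per 1000 live births,
# IGME-2017-style), the penetration index (female radio listenership 52% in
# the trial zones vs 45.2% nationally => 13.1% reduction), the 0/10/20%
# campaign-format discounts, and the same utilisation effects and treatment
# parameters as the trial-zone scenario.
#
# SYNTHETIC inputs: live births back-derived from the reported national
# per-year algebra; cause fractions, baseline coverages and the ANC/delivery
# parameters are illustrative, as in trial_scenario.yaml.
name: national-burkina
years: [2012, 2013, 2014]
envelope:
  u5mr: {2012: 103.3, 2013: 97.7, 2014: 92.8}
  live_births: {2012: 703900, 2013: 757200, 2014: 794500}
  cause_fractions:
    malaria: 0.20
    pneumonia: 0.17
    diarrhoea: 0.10
    intrapartum: 0.10
    neonatal_sepsis: 0.05
    prematurity: 0.11
population_scale: 1.0
penetration: {reference: 0.52, target: 0.452}
discounts: [0.0, 0.10, 0.20]
rural_adjustment: 1.0
interventions:
  - name: act_malaria
    effectiveness: 0.87
    affected_fraction: 1.0
    causes: [malaria]
    coverage_mode: treatment_with_receipt
    receipt: 0.543
    baseline_coverage: 0.33
    effect: malaria
  - name: oral_antibiotics_pneumonia
    effectiveness: 0.70
    affected_fraction: 1.0
    causes: [pneumonia]
    coverage_mode: careseeking_proxy
    baseline_coverage: 0.50
    effect: pneumonia
  - name: ors_diarrhoea
    effectiveness: 0.93
    affected_fraction: 1.0
    causes: [diarrhoea]
    coverage_mode: treatment_with_receipt
    receipt: 0.345
    baseline_coverage: 0.19
    effect: diarrhoea
  - name: skilled_delivery
    effectiveness: 0.25
    affected_fraction: {intrapartum: 0.8, neonatal_sepsis: 0.4}
    causes: [intrapartum, neonatal_sepsis]
    coverage_mode: direct
    baseline_coverage: 0.66
    effect: delivery
  - name: anc_bundle
    effectiveness: 0.10
    affected_fraction: 0.3
    causes: [prematurity]
    coverage_mode: direct
    baseline_coverage: 0.60
    effect: anc
utilisation_effects:
  malaria:
    point: [0.56, 0.37, 0.35]
    low: [0.30, 0.12, 0.09]
    high: [0.88, 0.69, 0.67]
  pneumonia:
    point: [0.39, 0.25, 0.11]
    low: [0.22, 0.05, -0.20]
    high: [0.58, 0.49, 0.54]
  diarrhoea:
    point: [0.73, 0.60, 1.07]
    low: [0.42, 0.12, 0.43]
    high: [1.10, 1.29, 2.00]
  anc:
    point: [0.06, 0.09, 0.08]
    low: [0.02, 0.03, 0.02]
    high: [0.10, 0.15, 0.14]
  delivery:
    point: [0.07, 0.06, 0.09]
    low: [0.02, 0.02, 0.04]
    high: [0.12, 0.10, 0.14]
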