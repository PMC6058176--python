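# Trial-zone scenario (intervention arm, 2012-2014).
#
# Printed inputs: campaign-year u5mr (137 / 126.5 / 105.1 per 1000 live
# births), treatment effectiveness (ACT 87%, oral antibiotics 70%, ORS 93%,
# affected fraction 1.0), receipt proportions (54.3% antimalarial among fever
# attenders, 34.5% ORS among diarrhoea attenders), and the utilisation
# effects with their 95% CIs for the three targeted illnesses.
#
# SYNTHETIC inputs (not published in the trial reports' main text): live
# births are back-derived from the reported per-year lives-saved /
# %-reduction algebra; cause-of-death fractions are a WHO-2011-style
# illustrative structure; baseline coverages, the ANC/delivery effect CIs
# and the ANC-bundle / delivery effectiveness values are illustrative
# placeholders, NOT Lives Saved Tool defaults.
name: trial-zone
years: [2012, 2013, 2014]
envelope:
  u5mr: {2012: 137.0, 2013: 126.5, 2014: 105.1}
  live_births: {2012: 112200, 2013: 113300, 2014: 113800}
  cause_fractions:
    malaria: 0.20
    pneumonia: 0.17
    diarrhoea: 0.10
    intrapartum: 0.10
    neonatal_sepsis: 0.05
    prematurity: 0.11
population_scale: 1.0
penetration: {reference: 0.52, target: 0.52}
discounts: [0.0]
rural_adjustment: 1.0
interventions:
  - name: act_malaria
    effectiveness: 0.87
    affected_fraction: 1.0
    causes: [malaria]
    coverage_mode: treatment_with_receipt
    receipt: 0.543
    baseline_coverage: 0.30
    effect: malaria
  - name: oral_antibiotics_pneumonia
    effectiveness: 0.70
    affected_fraction: 1.0
    causes: [pneumonia]
    coverage_mode: careseeking_proxy
    baseline_coverage: 0.47
    effect: pneumonia
  - name: ors_diarrhoea
    effectiveness: 0.93
    affected_fraction: 1.0
    causes: [diarrhoea]
    coverage_mode: treatment_with_receipt
    receipt: 0.345
    baseline_coverage: 0.17
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
  anc:  # point effects as reported; CI bounds illustrative
    point: [0.06, 0.09, 0.08]
    low: [0.02, 0.03, 0.02]
    high: [0.10, 0.15, 0.14]
  delivery:  # point effects as reported; CI bounds illustrative
    point: [0.07, 0.06, 0.09]
    low: [0.02, 0.02, 0.04]
    high: [0.12, 0.10, 0.14]
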