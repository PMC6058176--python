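# SYNTHETIC five-country scale-up fixture (2018-2020).
#
# The per-country envelopes, baseline coverages and media-penetration values
# in the source study live in supplementary material that is not reproduced
# here; every country-specific number below is an ILLUSTRATIVE placeholder
# chosen to be demographically plausible, and the file is named accordingly.
# The shared utilisation effects are the trial's reported effects; the
# treatment effectiveness/receipt parameters mirror trial_scenario.yaml.
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

countries:
  - name: burkina-faso
    years: [2018, 2019, 2020]
    envelope:
      u5mr: {2018: 81.0, 2019: 78.5, 2020: 76.0}
      live_births: {2018: 830000, 2019: 845000, 2020: 860000}
      cause_fractions: &cf
        malaria: 0.20
        pneumonia: 0.17
        diarrhoea: 0.10
        intrapartum: 0.10
        neonatal_sepsis: 0.05
        prematurity: 0.11
    penetration: {reference: 0.52, target: 0.452}
    discounts: [0.0, 0.10, 0.20]
    interventions: &ivs
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
  - name: burundi
    years: [2018, 2019, 2020]
    envelope:
      u5mr: {2018: 58.0, 2019: 56.0, 2020: 54.5}
      live_births: {2018: 440000, 2019: 450000, 2020: 460000}
      cause_fractions: *cf
    penetration: {reference: 0.52, target: 0.60}
    discounts: [0.0, 0.10, 0.20]
    interventions: *ivs
  - name: malawi
    years: [2018, 2019, 2020]
    envelope:
      u5mr: {2018: 50.0, 2019: 48.5, 2020: 47.0}
      live_births: {2018: 650000, 2019: 660000, 2020: 670000}
      cause_fractions: *cf
    penetration: {reference: 0.52, target: 0.70}
    discounts: [0.0, 0.10, 0.20]
    interventions: *ivs
  - name: mozambique
    years: [2018, 2019, 2020]
    envelope:
      u5mr: {2018: 73.0, 2019: 71.0, 2020: 69.0}
      live_births: {2018: 1100000, 2019: 1120000, 2020: 1140000}
      cause_fractions: *cf
    penetration: {reference: 0.52, target: 0.55}
    discounts: [0.0, 0.10, 0.20]
    interventions: *ivs
  - name: niger
    years: [2018, 2019, 2020]
    envelope:
      u5mr: {2018: 84.0, 2019: 81.5, 2020: 79.0}
      live_births: {2018: 1000000, 2019: 1030000, 2020: 1060000}
      cause_fractions: *cf
    penetration: {reference: 0.52, target: 0.50}
    discounts: [0.0, 0.10, 0.20]
    interventions: *ivs
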