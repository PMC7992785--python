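# Base-case inputs for the NASH-with-significant-fibrosis burden model.
#
# Published values (prevalence layers, transition probabilities, state costs,
# HCC/LT/post-LT death probabilities, the 2019 economics) are transcribed from
# the source study's input table.  Values the study does NOT print are
# synthetic, editable defaults and are marked "synthetic default" below:
#   - rr_nafld / rr_cirrhosis (mortality relative risks, cited but unprinted)
#   - initial_distribution (fibrosis-stage split of prevalent cases)
#   - entry_ages (representative band entry ages: band midpoints)
# reporting_band_overrides pin each reporting band's prevalence to the exact
# ratio printed-cohort / printed-population from the published prevalence
# table, so the case counts reproduce to the person.
schema_version: 1

economics:
  discount_rate: 0.03
  currency_year: 2019
  thb_per_usd: 32.3
  horizon_age: 100
  cycle_length_years: 1
  gdp_usd: 543.0e+9

mortality:
  rr_nafld: 1.57        # synthetic default (editable; source unprinted)
  rr_cirrhosis: 5.0     # synthetic default (editable; source unprinted)
  p_death_hcc: {value: 0.4490, se: 0.02959}
  p_death_lt: {value: 0.2007, se: 0.01024}
  p_death_post_lt: {value: 0.0653, se: 0.00333}

transitions:
  # progression
  - {source: NORMAL, target: F0, probability: 0.00140, age_band: 18-39}
  - {source: NORMAL, target: F0, probability: 0.00407, age_band: 40-59}
  - {source: NORMAL, target: F0, probability: 0.00515, age_band: 60-89}
  - {source: NORMAL, target: F0, probability: 0.00150, age_band: 90+}
  - {source: F0, target: F1, probability: 0.090, se: 0.026}
  - {source: F1, target: F2, probability: 0.140, se: 0.036}
  - {source: F2, target: F3, probability: 0.070, se: 0.020}
  - {source: F3, target: F4_CC, probability: 0.080, se: 0.020}
  - {source: F4_CC, target: DC, probability: 0.060, se: 0.010}
  - {source: F4_CC, target: HCC, probability: 0.030, se: 0.012}
  - {source: DC, target: HCC, probability: 0.030, se: 0.01173}
  - {source: DC, target: LT, probability: 0.0003, se: 0.00002}
  - {source: HCC, target: LT, probability: 0.0016, se: 0.00008}
  - {source: HCC, target: DEATH, probability: 0.4490, se: 0.02959}
  - {source: LT, target: POST_LT, probability: 0.7993, complement_of_death: true}
  - {source: LT, target: DEATH, probability: 0.2007, se: 0.01024}
  - {source: POST_LT, target: DEATH, probability: 0.0653, se: 0.00333}
  # regression
  - {source: F0, target: NORMAL, probability: 0.000}   # fixed by assumption
  - {source: F1, target: F0, probability: 0.080, se: 0.026}
  - {source: F2, target: F1, probability: 0.190, se: 0.059}
  - {source: F3, target: F2, probability: 0.200, se: 0.087}
  - {source: F4_CC, target: F3, probability: 0.120, se: 0.023}

costs:   # 2019 USD per person-year
  NASH: {value: 89, se: 11}
  CC: {value: 2121, se: 271}
  DC: {value: 3916, se: 499}
  HCC: {value: 4787, se: 622}
  LT: {value: 18703, se: 2298}
  POST_LT: {value: 2908, se: 371}

prevalence:
  nafld_in_population:
    - {age_band: 18-39, value: 0.353, se: 0.013}
    - {age_band: 40-59, value: 0.348, se: 0.002}
    - {age_band: 60+, value: 0.244, se: 0.004}
  nash_in_nafld:
    - {age_band: 18-29, value: 0.183, se: 0.009}
    - {age_band: 30-39, value: 0.224, se: 0.011}
    - {age_band: 40-49, value: 0.169, se: 0.009}
    - {age_band: 50-59, value: 0.164, se: 0.008}
    - {age_band: 60-69, value: 0.152, se: 0.008}
    - {age_band: 70-79, value: 0.090, se: 0.005}
    - {age_band: 80+, value: 0.090, se: 0.005}

# Exact printed-cohort / printed-population ratios from the published
# prevalence table (model outputs whose derivation weighting is unpublished).
reporting_band_overrides:
  - {age_band: 18-39, nafld_prevalence: 0.351244749139, nash_prevalence: 0.071399386065}
  - {age_band: 40-59, nafld_prevalence: 0.344857518887, nash_prevalence: 0.058026361421}
  - {age_band: 60+, nafld_prevalence: 0.225682173559, nash_prevalence: 0.030529741267}

# Synthetic default (editable): stage split of prevalent significant-NASH
# cases at model entry; older bands carry more advanced disease.
initial_distribution:
  - {age_band: 18-39, F2: 0.70, F3: 0.25, F4_CC: 0.04, DC: 0.007, HCC: 0.003}
  - {age_band: 40-59, F2: 0.55, F3: 0.30, F4_CC: 0.11, DC: 0.025, HCC: 0.015}
  - {age_band: 60+, F2: 0.35, F3: 0.33, F4_CC: 0.22, DC: 0.06, HCC: 0.04}

# Synthetic default: representative entry age per reporting band (midpoints;
# 70 for the open-ended 60+ band).
entry_ages:
  - {age_band: 18-39, age: 28.5}
  - {age_band: 40-59, age: 49.5}
  - {age_band: 60+, age: 70}
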