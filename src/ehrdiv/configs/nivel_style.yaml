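# Heavily-processed ETL rule-set: quarters from quarterly capitation-fee
# records with gaps between first and last record imputed; pseudonyms from the
# social security number (patients without one are lost); claims filtered to a
# study-relevant code selection; prescriptions include pharmacy feedback and
# are deduplicated within an 8-day window; episodes rebuilt with the
# episode construct over the analysis year plus two prior years.
name: nivel_style
quarter_rule: from_capitation_imputed
pseudonym_scheme: ssn
claims_filter: ["12001", "12002", "12003", "12010", "12011", "13012", "13034", "12004"]
contact_codes_filter: null
dedup_window_days: 8
include_pharmacy_prescriptions: true
episode_mode: construct
lookback_years: 2
contact_free_interval_days:
  U71: 28
  R05: 90
default_contact_free_interval_days: 90
chronic_codes: [T90]
collapse_pseudonym_collisions: true
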