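# Registry-style ETL rule-set: take the EHR content largely as recorded.
# Quarters from the enrollment date (full quarters only, mid-quarter
# enrollment starts the next quarter); pseudonyms from postal-code prefix +
# birth year + sex; all insurance claims codes kept; GP prescriptions only,
# no deduplication; episodes as recorded by the GP.
name: ahon_style
quarter_rule: from_enrollment_date
pseudonym_scheme: pc3_birthyear_sex
claims_filter: all
contact_codes_filter: null
dedup_window_days: 0
include_pharmacy_prescriptions: false
episode_mode: recorded
lookback_years: 2
contact_free_interval_days: {}
default_contact_free_interval_days: 90
chronic_codes: [T90]
collapse_pseudonym_collisions: true
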