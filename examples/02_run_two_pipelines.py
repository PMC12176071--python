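"""Run the two shipped ETL rule-sets on one extract and compare their shape.

The registry-style rule-set (ahon_style) keeps the EHR content largely as
recorded; the heavily-processed rule-set (nivel_style) derives quarters from
capitation records, filters claims codes, deduplicates prescriptions within
8 days, and rebuilds episodes with the episode construct.
"""

import ehrdiv as ed

cfg = ed.GeneratorConfig(
    n_practices=2, patients_per_practice_mean=300, patients_per_practice_sd=30, seed=20190101
)
extract = ed.generate_extract(cfg)

for rule_set in (ed.ahon_style(), ed.nivel_style()):
    ds = ed.run_pipeline(extract, rule_set, 2019)
    py = ed.patient_years_total(ds)
    print(
        f"{rule_set.name:12s} patients={len(ds.patients):4d} "
        f"patient_years={py:7.2f} contacts={len(ds.contacts):5d} "
        f"prescriptions={len(ds.prescriptions):5d} episodes={len(ds.episodes):4d}"
    )

# Same raw data, different research datasets: the SSN scheme loses patients
# with a missing identifier, capitation gaps trim person-time, the claims
# filter removes contact-days, and the construct multiplies episodes.
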