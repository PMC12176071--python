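# Methods

`ehrdiv` quantifies how extraction-transformation-loading (ETL) choices in
the "database zone" — the processing between a general practice's EHR export
and a research-ready dataset — change research outcomes. Because the
original registry data cannot be redistributed, the package pairs a
synthetic general-practice EHR generator with two fully specified ETL
rule-sets and a three-step comparison, so every processing contrast can be
measured end to end on data with known ground truth.

## The two ETL rule-sets

Each rule-set is a `PipelineConfig`; the shipped pair contrasts a
registry-style pipeline (`ahon_style`) with a heavily-processed one
(`nivel_style`). Rule by rule:

| rule | `ahon_style` | `nivel_style` |
|---|---|---|
| registration quarters | from the enrollment date; only fully covered quarters count, mid-quarter enrollment starts the next quarter | from quarterly capitation-fee records; missing quarters between the first and last record are imputed, no extrapolation |
| pseudonym | keyed hash of (practice upload, first 3 postal digits, birth year, sex); collisions collapse to one patient with the union of events | keyed hash of the social security number; patients without one are dropped |
| insurance claims | all codes kept | filtered to a study-relevant code selection |
| contacts | one per distinct (patient, day) with any retained claims code | same rule, applied after the code filter |
| prescriptions | GP-recorded only, no deduplication | GP and pharmacy-feedback records, deduplicated when the same ATC code recurs within 8 days |
| episodes | as recorded in the EHR, restricted to those overlapping the analysis year | rebuilt with the episode construct (below) |

A patient enters a dataset only with at least one registered quarter in the
analysis year; patient years are 0.25 x quarters, so each patient
contributes between 0.25 and 1.0 person-years.

**Deduplication.** The 8-day rule is implemented as a greedy scan per
(patient, ATC) group in date order: a record is dropped iff it falls at most
`window` days (boundary inclusive) after the last *kept* record. This keeps
the first record of a burst and admits a new record once the gap from the
last kept record exceeds the window; it is idempotent and never increases
row counts. Window 0 collapses only exact same-day duplicates.

**Episode construct.** Per (patient, ICPC code), encounter dates are pooled
from coded journal contacts, prescriptions carrying that indication, and the
start dates of recorded episode records, over the analysis year plus
`lookback_years` (default 2) prior years. Before pooling, a symptom contact
filed under an episode with a different code takes the episode's code (a
cough contact under an asthma episode becomes asthma). Encounters are
sorted; a gap larger than the code's contact-free interval L starts a new
episode; each episode runs from its first encounter to its last encounter
plus `floor(L/2)` days. "Half the contact-free interval" is read as half of
the *configured* per-code interval, not half the observed gap — the
observed-gap reading is undefined for single-encounter episodes. Codes in
`chronic_codes` yield a single never-closing episode from the first
encounter. L defaults to 90 days, configurable per code (the shipped
`nivel_style` uses 28 days for U71); the exact intervals used by the source
registries are not public, so these values are illustrative. Recorded episode
end dates do not constrain the construct for non-chronic codes: the construct
re-derives ends, which matches its purpose of imposing end dates
independently of GP recording habits.

## Linkage and the comparison

Both processed datasets receive platform person identifiers from a
registry: SSN-derived pseudonyms resolve deterministically, pc3-derived
pseudonyms resolve only when the (practice, PC3, birth year, sex) key is
unique — ambiguous keys are unlinkable, which is the mechanism behind
concordant-group loss. In the simulation the generator's person key plays
the role of the national identifier.

* **Step 1 (all patients):** counts, patient years, patients per practice,
  age bands 0-4 / 5-17 / 18-64 / 65+, sex.
* **Step 2 (concordant patients):** per-patient counts of contacts, regular
  consultations and visits (claims codes 12001/12002/12003/12010/12011, at
  most one per patient-day), prescriptions, and episodes overlapping the
  analysis year, compared by paired t tests with a CI of the mean difference
  (sign convention: dataset A minus dataset B). The confidence level is a
  parameter, default 0.95. Zero-variance differences (e.g. identical inputs)
  are flagged `degenerate` rather than dividing by zero.
* **Step 3 (all patients):** for diabetes (T90), urinary tract infection
  (U71) and cough (R05): prevalence per 1000 patient years (a case is a
  patient with at least one claims-linked ICPC record in the analysis year,
  counted once), prescriptions per 1000 patient years from the group's ATC
  prefixes (A10A/A10B; G03C/J01C/J01D/J01E/J01G/J01M/J01X;
  R05C/R05D/R05X/R06A), and the case patients' regular consultations per
  1000 patient years. Rates are compared as per-patient-year proportions
  (rate/1000) with the standardized difference
  SD = (p_a - p_b) / sqrt[(p_a(1-p_a) + p_b(1-p_b))/2], banded at
  0.2/0.5/0.8 (small/medium/large) and flagged significant when |SD| > 0.2.
  The rate denominator is configurable (`total_py`, the default, or
  `group_py`), and consults are attributed as *all* regular consults of the
  case patients; both choices are genuinely underdetermined in registry
  practice and are therefore parameters rather than fixed rules. No
  multiple-testing correction is applied.

Rates and percentages are rounded (1 decimal; SDs to 2) only at table
rendering; `report.json` keeps unrounded values.

## The synthetic population

Defaults describe the emulated study conditions: 8 practices averaging
5,750 enrolled patients (SD 650), age bands at 4.7/15.5/57.9/21.9%, 50.6%
female, an event window 2017-01-01 to 2019-12-31 with analysis year 2019.
Most patients span the whole window; 5% either enroll at a uniform date in
the window or disenroll during the analysis year, putting mean patient
years per patient near 0.98. Capitation-fee records exist for every quarter
fully covered by the enrollment span, each dropped independently with
probability 0.02 — interior gaps are recoverable by imputation, edge gaps
are not, which is exactly the contrast the two quarter rules probe.

Conditions: chronic T90 (6.5%), K86 (9%), R96 (3%) generate 1 + Poisson(2)
coded contacts per year from onset (onset up to 5 years before the window);
acute U71 (6.5%/year), R05 (5.5%/year), L03 (4%/year) generate a
1 + Poisson(0.7)-contact burst within three weeks. Every coded contact
produces a same-day claims event billed as a regular consultation with
probability 0.95; uncoded background claims events top total volume up to
8.5 claims per patient-year. Prescriptions come from per-condition ATC
rates (e.g. metformin 4/year for T90) plus background drugs on 55% of
background claims; 5% of records originate from pharmacy feedback, and 10%
acquire a near-duplicate record 0-8 days later from the other source. GPs
record an episode for 90% of chronic conditions and 50% of acute illnesses
(70% of recorded acute episodes get an end date); 20% of cough contacts of
asthma patients are filed under the asthma episode. These recording-habit
constants are module-level values in `ehrdiv.synthetic`, not config fields.

The T90/U71/R05 rates sit in the 5-7% band and the utilisation means (4-9
events per patient) in the range typical of Dutch general practice; the
source practices' true distributions are not public, so these magnitudes are
illustrative calibrations, not estimates.

**Pseudonym collisions.** The pc3 pseudonym is scoped to one practice
upload. An unscoped (PC3, birth year, sex) triple collides for roughly a
quarter of a 46,000-patient population no matter how many 3-digit prefixes
exist, which would collapse enough patients to visibly inflate
person-time-based rates — behaviour the real registries demonstrably do not
show. Practice scoping with the default 800-prefix pool keeps collisions at
a few percent: present and exercised, but not dominant. Postal geography is
deliberately unrealistic (prefixes are uniform draws).

**What passing tests do and do not show.** The generator reproduces the
*structure* the ETL rules act on (sources, codes, double records, gaps), not
real recording behaviour: no inter-practice or inter-GP variation in coding
habit, no seasonality, no comorbidity correlation, no free text, no vendor
dialects. Results on synthetic data validate that each rule does what it
says and how rule contrasts propagate into indicators; they do not estimate
the magnitudes of those contrasts in any real registry pair.

## Numerical and design notes

* Dates are day-granular; all intervals closed; ICPC/ATC/claims codes are
  opaque strings (format-checked only; ATC matching is by prefix).
* Pseudonyms are keyed BLAKE2b hashes with fixed package keys —
  deterministic across runs by design, since reproducibility, not secrecy,
  is the goal here.
* Determinism: one integer seed pins the generator; pipelines are
  deterministic transforms; `run_demo(seed, ...)` therefore reproduces
  byte-identical `report.json` files.
* Expected prevalence recovery carries a small upward bias by construction:
  cases are counted per patient while person-time averages ~0.98
  years/patient, so a 6.5% annual probability yields ~66-67 rather than 65
  per 1000 patient years; the recovery test averages over 20 seeds and
  checks against a single-extract binomial standard error.
* Problem sizes in the test suite: unit and property tests run on ~400- and
  ~10,000-patient extracts; the parameter-recovery check runs 20 seeds at
  the full ~46,000-patient scale, the oracle-equivalence checks on 1,000
  randomised small cases.
* Degenerate inputs: empty extracts round-trip; empty claims filters warn
  and return empty; a standardized difference with both proportions
  degenerate (0 or 1) raises rather than fabricating a value; paired tests
  need n >= 2.

## Known limitations

* The concordant fraction of the default synthetic population (~91-95%) is
  higher than typically seen in practice; it is driven only by missing SSNs
  and pc3 ambiguity, whereas real registries also lose patients to coverage
  and timing differences that are not modelled.
* The prescription-count contrast between the two rule-sets is small under
  the defaults (near-duplicates are largely removed symmetrically); the
  contrast direction observed in real registry pairs depends on recording
  practices the generator does not model.
* Claims codes attached to capitation fees are kept in their own table and
  never enter contact derivation; registries that bill capitation through
  the claims stream would show larger contact contrasts.
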