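# Cohort CSV column dictionary

One row per first allogeneic HSCT. RFC-4180 CSV, UTF-8, header row. Empty
cells mean missing. Alternate column names can be mapped via the `schema`
argument of `read_cohort`.

| column | type | values / units | required |
|---|---|---|---|
| `record_id` | string | opaque identifier | yes |
| `patient_age` | float | years at transplant | model field |
| `patient_sex` | category | `M`, `F` | no |
| `diagnosis_label` | string | one of the 19 disease entities (see below) | either this or `diagnosis_group` |
| `diagnosis_group` | int | `1`, `2`, `3` | model field |
| `disease_status` | category | e.g. `CR1`, `not_in_remission` | no |
| `comorbidity_class` | category | `0`, `1`, `2plus` | model field |
| `karnofsky` | int | 0–100 | no |
| `patient_cmv` | category | `pos`, `neg` | no |
| `donor_type` | category | `SIB`, `MUD`, `HAPLO` (others filtered out) | model field |
| `donor_age` | float | years at donation | model field |
| `donor_sex` | category | `M`, `F`, empty | no |
| `donor_cmv` | category | `pos`, `neg` | no |
| `followup_days` | int ≥ 0 | days, transplant → death or last contact | yes |
| `death_event` | bool | `1`/`0`, `true`/`false` | yes |
| `first_hsct` | bool | default `1` | no |
| `multiple_donor` | bool | default `0` | no |
| `planned_multigraft` | bool | default `0` | no |

"Model field" columns are required by the default survival model; records
missing one are removed (and counted) by `apply_eligibility_filters`.

Diagnosis groups: **1** — acute undifferentiated leukemia; acute myeloid
leukemia and related precursor neoplasms; mixed phenotype acute leukemia;
mixed phenotype B/myeloid; secondary acute leukemia; precursor lymphoid
neoplasms. **2** — chronic leukemia; chronic myeloid leukemia;
myeloproliferative neoplasia; myelodysplastic syndrome or myeloproliferative
syndrome; myelodysplastic syndrome; myelodysplastic and myeloproliferative
syndromes. **3** — Hodgkin's lymphoma; chronic lymphocytic leukemia;
Non-Hodgkin's lymphoma; lymphoma (not otherwise specified); prolymphocytic
leukemia; multiple myeloma; plasma cell leukemia.

# Design-matrix columns (default specification)

`Intercept`, `Diagnosis_2`, `Diagnosis_3`, `HLA_2` (MUD), `HLA_3`
(haploidentical), optional `Comorbidity_1`/`Comorbidity_2plus`,
`AgePatient`, `AgeDonor`, then the interaction columns
`AgePatient:Diagnosis_{2,3}`, `HLA_{2,3}:AgePatient`, `HLA_{2,3}:AgeDonor`,
`Diagnosis_{2,3}:AgeDonor`. Dummy columns are 0/1 against the reference
levels (diagnosis group 1, HLA-identical sibling, comorbidity 0); ages are
raw years; interaction columns are elementwise products of their parents.
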