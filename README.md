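# donorcalc

A donor-selection calculator for allogeneic hematopoietic stem-cell
transplantation (HSCT). When a patient has several potential stem-cell
donors — an HLA-identical sibling, a matched unrelated donor (MUD), one or
more haploidentical relatives — `donorcalc` predicts the patient's 2-year
overall survival (OS) under each option from a parametric survival model
fitted to a transplant center's own cohort, and presents the options ranked,
with confidence intervals and hazard ratios. It is decision support for
transplant physicians: it orders and annotates the options, it does not pick
one.

## The model

Survival time after transplant is modelled with a Weibull accelerated
failure time (AFT) regression. With covariate row $x$, the log survival
time satisfies

$$\log T = \beta_0 + \sum_i \beta_i x_i + \sum_{i<j} \beta_{ij} x_i x_j + \tfrac{1}{k}\,W,$$

where $W$ follows the standard smallest-extreme-value distribution and $k$
is the Weibull shape ($\sigma = 1/k$ is the AFT scale). Equivalently
$S(t \mid x) = \exp\!\big(-(t\,e^{-\mu})^k\big)$ with linear predictor
$\mu = \beta \cdot x$. Covariates are the diagnosis group (1 acute
leukemias, 2 chronic myeloid/MDS/MPN, 3 lymphoid/plasma-cell), the donor
type ("HLA": sibling / MUD / haploidentical), the comorbidity class
(0 / 1 / ≥2), patient and donor age (raw years), and the pairwise
interactions age×diagnosis, donor-type×patient-age, donor-type×donor-age and
diagnosis×donor-age. Estimation is right-censored maximum likelihood in
$(\beta, \log k)$; between-donor comparisons use the Weibull PH identity
$\mathrm{HR} = e^{-k\,\Delta\mu}$.

The package ships a published two-center coefficient set (737 first
allogeneic HSCTs, 294 deaths) as its default model, plus: censoring-aware
validation (Harrell's C, IPCW Brier score, event-stratified k-fold
cross-validation), an AFT family comparison on Cox–Snell residuals, and a
synthetic-cohort generator reproducing the cohort's structure so the whole
pipeline is testable end to end.

## Worked example

A 45-year-old patient with acute leukemia (diagnosis group 1), no
comorbidities, and four donor options:

```sh
donorcalc compare --patient-age 45 --diagnosis-group 1 \
  --donor SIB:45:sib-45 --donor MUD:30:mud-30 \
  --donor HAPLO:20:haplo-20 --donor HAPLO:45:haplo-45
```

```
Patient: age 45, diagnosis group 1, comorbidity 0
Horizon: 730 days | HR reference: sib-45
Donor                     Type  Age      OS            95% CI     HR
sib-45                     SIB   45   0.856                --  1.000
haplo-45                 HAPLO   45   0.836                --  1.153
mud-30                     MUD   30   0.828                --  1.216
haplo-20                 HAPLO   20   0.796                --  1.472
```

The sibling option gives the highest predicted 2-year OS, 0.856; the other
options trail it and carry hazard ratios above 1 against the sibling
reference. Confidence intervals print as `--` here because the bundled
coefficient set has no covariance matrix; fit the model on a cohort
(`donorcalc fit`) to obtain them.

The same query in Python:

```python
from donorcalc import (PatientProfile, DonorOption, compare_donor_options,
                       reference_model, reference_spec, render_report)

patient = PatientProfile(patient_age=45, diagnosis_group=1)
donors = [DonorOption("sib-45", "SIB", 45), DonorOption("mud-30", "MUD", 30)]
report = compare_donor_options(reference_model(), patient, donors,
                               reference_spec(), horizon=730)
print(render_report(report, "text"))
```

Fitting and validating on your own (or a simulated) cohort:

```sh
donorcalc simulate --n 737 --seed 1 --out cohort.csv
donorcalc fit cohort.csv --out model.json --summary
donorcalc validate cohort.csv --folds 5 --seed 1
```

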