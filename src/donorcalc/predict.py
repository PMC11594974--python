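"""Horizon-specific survival prediction and between-donor hazard ratios.

Given a fitted Weibull AFT model, a patient profile and a donor option, this
module computes the linear predictor mu, the survival probability
S(t) = exp(-(t e^{-mu})^k) at a horizon (default 2 years = 730 days), a
delta-method confidence interval for it, and the Weibull
proportional-hazards identity HR = exp(-k (mu_a - mu_b)) for comparing two
donors for the same patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import stats

from .aft import AFTParameters, FittedAFT, NoCovarianceError
from .design import DONOR_TYPE_TO_HLA, EncodingError, ModelSpec, encode_profile

#: Default prediction horizon: 2 years in days.
TWO_YEARS = 730

#: Age supports observed in the modelled cohorts; predictions outside warn.
PATIENT_AGE_RANGE = (21.0, 71.0)
DONOR_AGE_RANGE = (19.0, 58.0)


@dataclass
class PatientProfile:
    """The patient half of a calculator query."""

    patient_age: float
    diagnosis_group: int
    comorbidity_class: str = "0"
    disease_status: Optional[str] = None

    def __post_init__(self):
        lo, hi = PATIENT_AGE_RANGE
        if not (lo <= self.patient_age <= hi):
            warnings.warn(f"patient age {self.patient_age} outside the modelled "
                          f"support [{lo}, {hi}]; prediction is an extrapolation",
                          stacklevel=3)


@dataclass
class DonorOption:
    """One candidate donor: type (SIB/MUD/HAPLO) and age."""

    label: str
    donor_type: str
    donor_age: float

    def __post_init__(self):
        if self.donor_type not in DONOR_TYPE_TO_HLA:
            raise EncodingError(f"unknown donor type {self.donor_type!r}; "
                                f"expected one of {tuple(DONOR_TYPE_TO_HLA)}")
        lo, hi = DONOR_AGE_RANGE
        if not (lo <= self.donor_age <= hi):
            warnings.warn(f"donor age {self.donor_age} outside the modelled "
                          f"support [{lo}, {hi}]; prediction is an extrapolation",
                          stacklevel=3)


@dataclass
class PredictionResult:
    mu: float                 # linear predictor, log days
    survival: float           # S(horizon)
    ci: Optional[tuple[float, float]]
    horizon: float            # days


def _query_profile(profile: PatientProfile, donor: DonorOption,
                   spec: ModelSpec) -> dict[str, object]:
    prof: dict[str, object] = {
        "Diagnosis": str(profile.diagnosis_group),
        "HLA": DONOR_TYPE_TO_HLA[donor.donor_type],
        "AgePatient": float(profile.patient_age),
        "AgeDonor": float(donor.donor_age),
    }
    factor_names = {f.name for f in spec.factors}
    if "Comorbidity" in factor_names:
        prof["Comorbidity"] = profile.comorbidity_class
    if "DiseaseStatus" in factor_names:
        status = profile.disease_status or "CR"
        prof["DiseaseStatus"] = "CR" if str(status).upper().startswith("CR") else "not_CR"
    return prof


def encode_query(profile: PatientProfile, donor: DonorOption,
                 spec: ModelSpec) -> np.ndarray:
    """Design row for one patient-donor query."""
    return encode_profile(_query_profile(profile, donor, spec), spec)


def linear_predictor(model: AFTParameters, profile: PatientProfile,
                     donor: DonorOption, spec: ModelSpec) -> float:
    """mu = beta . x for the encoded patient-donor query (log days)."""
    x = encode_query(profile, donor, spec)
    return float(model.beta_vector(spec.column_names) @ x)


def survival_probability(mu: float, shape_k: float, t: float) -> float:
    """Weibull AFT survival S(t) = exp(-(t e^{-mu})^k)."""
    if t < 0:
        raise ValueError("horizon must be non-negative")
    if shape_k <= 0:
        raise ValueError("shape must be positive")
    if t == 0:
        return 1.0
    return float(np.exp(-np.exp(shape_k * (np.log(t) - mu))))


def median_survival_time(mu: float, shape_k: float) -> float:
    """Time at which S(t) = 0.5: exp(mu + log(log 2)/k)."""
    return float(np.exp(mu + np.log(np.log(2.0)) / shape_k))


def _sev_z_and_gradient(fit: FittedAFT, x: np.ndarray, t: float):
    """Standardized SEV residual z(t) = k (log t - mu) and its gradient in
    (beta, log k).  S(t) = exp(-e^z), so the survival CI is the monotone
    image of a Wald interval on z."""
    k = fit.params.shape_k
    mu = float(fit.params.beta_vector() @ x)
    z = k * (np.log(t) - mu)
    grad = np.append(-k * x, z)   # d z / d beta = -k x ; d z / d log k = z
    return z, grad


def survival_ci(fit: FittedAFT, profile: PatientProfile, donor: DonorOption,
                spec: ModelSpec, t: float = TWO_YEARS,
                level: float = 0.95) -> tuple[float, float]:
    """Delta-method confidence interval for S(t), computed on the
    smallest-extreme-value linearized scale so endpoints stay inside (0, 1).

    Requires a covariance matrix over (beta, log k); coefficient-only
    fixtures raise :class:`NoCovarianceError`.
    """
    cov = fit.require_covariance()
    x = encode_query(profile, donor, spec)
    z, grad = _sev_z_and_gradient(fit, x, t)
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    zstar = stats.norm.ppf(0.5 + level / 2)
    # S = exp(-e^z) is decreasing in z: upper z bound -> lower survival bound
    lo = float(np.exp(-np.exp(z + zstar * se)))
    hi = float(np.exp(-np.exp(z - zstar * se)))
    return lo, hi


def predict_survival(model, profile: PatientProfile, donor: DonorOption,
                     spec: ModelSpec, t: float = TWO_YEARS,
                     level: float = 0.95) -> PredictionResult:
    """Point prediction, with a CI when ``model`` is a fit with covariance."""
    if isinstance(model, FittedAFT):
        params, fit = model.params, model
    else:
        params, fit = model, None
    mu = linear_predictor(params, profile, donor, spec)
    s = survival_probability(mu, params.shape_k, t)
    ci = None
    if fit is not None and fit.covariance is not None:
        ci = survival_ci(fit, profile, donor, spec, t, level)
    return PredictionResult(mu=mu, survival=s, ci=ci, horizon=float(t))


def hazard_ratio(model, profile: PatientProfile, donor_a: DonorOption,
                 donor_b: DonorOption, spec: ModelSpec,
                 level: float = 0.95):
    """Hazard ratio of donor_a versus donor_b for the same patient.

    Uses the Weibull PH-AFT identity HR = exp(-k (mu_a - mu_b)); HR > 1
    means donor_a carries the higher hazard.  When ``model`` is a fit with a
    covariance matrix, a delta-method CI on log HR = -k (mu_a - mu_b) is
    returned as well; otherwise the CI is ``None``.
    """
    if isinstance(model, FittedAFT):
        params, cov = model.params, model.covariance
    else:
        params, cov = model, None
    xa = encode_query(profile, donor_a, spec)
    xb = encode_query(profile, donor_b, spec)
    beta = params.beta_vector(spec.column_names)
    k = params.shape_k
    dmu = float(beta @ (xa - xb))
    log_hr = -k * dmu
    hr = float(np.exp(log_hr))
    if cov is None:
        return hr, None
    # gradient of log HR in (beta, log k): -k (xa - xb), and -k dmu = log HR
    grad = np.append(-k * (xa - xb), log_hr)
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    zstar = stats.norm.ppf(0.5 + level / 2)
    return hr, (float(np.exp(log_hr - zstar * se)), float(np.exp(log_hr + zstar * se)))
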