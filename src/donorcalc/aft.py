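"""Weibull accelerated-failure-time regression with right censoring.

The model: survival time T given covariate row x follows a Weibull
distribution with scale exp(mu) and shape k, where mu = beta . x is the
linear predictor on the log-day scale.  Equivalently log T = mu + W/k with W
standard smallest-extreme-value, so the AFT scale parameter sigma equals 1/k
and the p-th log-survival-time quantile is mu + log(-log(1-p))/k.  Positive
coefficients stretch survival time; k > 1 means an increasing hazard.

Estimation is unconstrained maximum likelihood in (beta, log k) with analytic
gradient and Hessian; the covariance matrix is the inverse observed
information on that scale.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy import stats

from .design import DesignMatrix

Z975 = stats.norm.ppf(0.975)


class DomainError(ValueError):
    """Likelihood evaluated outside its domain (t <= 0 or shape <= 0)."""


class RankDeficientError(ValueError):
    """The design matrix is not full column rank."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to reach the gradient tolerance."""


class NoCovarianceError(ValueError):
    """Operation requires a covariance matrix the model does not carry."""


@dataclass
class AFTParameters:
    """Coefficients (log-days per unit covariate) and Weibull shape k > 0."""

    beta: dict[str, float]
    shape_k: float

    def __post_init__(self):
        if self.shape_k <= 0:
            raise DomainError(f"shape must be positive, got {self.shape_k}")

    @property
    def column_names(self) -> list[str]:
        return list(self.beta)

    def beta_vector(self, columns: Optional[Sequence[str]] = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.column_names
        missing = [c for c in cols if c not in self.beta]
        if missing:
            raise KeyError(f"coefficients missing for columns: {missing}")
        return np.array([self.beta[c] for c in cols])

    @property
    def sigma(self) -> float:
        """AFT scale of log survival time (reciprocal of the shape)."""
        return 1.0 / self.shape_k


@dataclass
class FittedAFT:
    """A maximum-likelihood fit with inference metadata.

    ``covariance`` is over (beta, log k), shape (p+1, p+1), with log k last;
    it is ``None`` for coefficient-only fixtures, in which case operations
    needing it raise :class:`NoCovarianceError`.
    """

    params: AFTParameters
    covariance: Optional[np.ndarray]
    loglik: Optional[float]
    n: Optional[int]
    n_events: Optional[int]
    converged: bool = True
    iterations: int = 0

    def require_covariance(self) -> np.ndarray:
        if self.covariance is None:
            raise NoCovarianceError(
                "model carries no covariance matrix (coefficient-only fixture); "
                "confidence intervals are unavailable — refit on cohort data")
        return self.covariance

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": "weibull_aft",
            "coefficients": self.params.beta,
            "shape": self.params.shape_k,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "covariance_order": self.params.column_names + ["log_shape"],
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "iterations": self.iterations,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedAFT":
        cov = d.get("covariance")
        return cls(
            params=AFTParameters(beta=dict(d["coefficients"]), shape_k=float(d["shape"])),
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            loglik=d.get("loglik"),
            n=d.get("n"),
            n_events=d.get("n_events"),
            converged=bool(d.get("converged", True)),
            iterations=int(d.get("iterations", 0)),
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedAFT":
        return cls.from_dict(json.loads(text))


def _check_design(design: DesignMatrix) -> None:
    if np.any(design.times <= 0):
        raise DomainError("all survival times must be positive; "
                          "shift zero-day follow-ups first (see prepare_times)")


def prepare_times(times: np.ndarray, zero_shift: float = 0.5) -> np.ndarray:
    """Replace zero follow-up times with ``zero_shift`` days (with a warning).

    The Weibull likelihood is undefined at t = 0; day-0 deaths are recorded
    in registries and must be nudged off zero before fitting.
    """
    times = np.asarray(times, dtype=float)
    nz = times == 0
    if nz.any():
        warnings.warn(f"{int(nz.sum())} zero-day follow-up time(s) shifted to "
                      f"{zero_shift} days", stacklevel=2)
        times = times.copy()
        times[nz] = zero_shift
    return times


def log_likelihood(params: AFTParameters, design: DesignMatrix) -> float:
    """Right-censored Weibull AFT log-likelihood.

    Events contribute log f(t) = log k - k*mu + (k-1) log t - (t e^{-mu})^k;
    censored records contribute log S(t) = -(t e^{-mu})^k.
    """
    _check_design(design)
    beta = params.beta_vector(design.column_names)
    k = params.shape_k
    mu = design.X @ beta
    w = k * (np.log(design.times) - mu)
    r = np.exp(w)
    d = design.events
    return float(np.sum(d * (np.log(k) - np.log(design.times) + w)) - np.sum(r))


def _nll_grad_hess(theta: np.ndarray, X: np.ndarray, logt: np.ndarray,
                   d: np.ndarray, order: int = 2):
    """Negative log-likelihood, gradient and (optionally) Hessian in
    theta = (beta, log k)."""
    beta, logk = theta[:-1], theta[-1]
    k = np.exp(logk)
    mu = X @ beta
    w = k * (logt - mu)
    # guard against overflow in exp for wildly wrong trial points
    r = np.exp(np.clip(w, -700, 700))
    ll = np.sum(d * (logk - logt + w)) - np.sum(r)
    g_beta = -k * X.T @ (d - r)
    g_logk = np.sum(d) + np.sum((d - r) * w)
    grad = np.append(g_beta, g_logk)
    if order < 2:
        return -ll, -grad, None
    H_bb = -(k * k) * (X.T * r) @ X
    h_bl = k * ((r * w - (d - r)) @ X)
    h_ll = np.sum((d - r) * w) - np.sum(r * w * w)
    H = np.empty((len(theta), len(theta)))
    H[:-1, :-1] = H_bb
    H[:-1, -1] = h_bl
    H[-1, :-1] = h_bl
    H[-1, -1] = h_ll
    return -ll, -grad, -H


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    bad = [columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad or X.shape[1] > len(diag):
        raise RankDeficientError(f"design matrix is rank deficient; "
                                 f"collinear columns include {bad}")


def fit_weibull_aft(design: DesignMatrix, gtol: float = 1e-8,
                    max_iter: int = 500, zero_shift: float = 0.5) -> FittedAFT:
    """Fit the Weibull AFT model by maximum likelihood.

    Deterministic quasi-Newton optimization (BFGS with analytic gradient,
    Newton polishing) in (beta, log k), initialized from the intercept-only
    exponential fit: intercept log(total time / events), other coefficients 0,
    k = 1.  Non-convergence is flagged on the result, never silent.
    """
    if design.n_events < 1:
        raise ValueError("at least one observed event is required")
    _check_rank(design.X, design.column_names)
    times = prepare_times(design.times, zero_shift)
    X, d = design.X, design.events.astype(float)
    logt = np.log(times)
    p = X.shape[1]

    theta0 = np.zeros(p + 1)
    has_intercept = np.all(X[:, 0] == 1.0)
    if has_intercept:
        theta0[0] = np.log(times.sum() / d.sum())  # exponential rate MLE

    res = scipy.optimize.minimize(
        lambda th: _nll_grad_hess(th, X, logt, d, order=1)[:2],
        theta0, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter})
    theta = res.x
    # Newton polishing to the gradient sup-norm tolerance
    iterations = int(res.nit)
    for _ in range(50):
        nll, grad, H = _nll_grad_hess(theta, X, logt, d)
        if np.max(np.abs(grad)) <= gtol:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking line search; near the optimum the objective decrease
        # is below float resolution, so a gradient-norm decrease also counts
        gnorm = np.max(np.abs(grad))
        t = 1.0
        while t > 1e-8:
            cand = theta - t * step
            c_nll, c_grad, _ = _nll_grad_hess(cand, X, logt, d, order=1)
            if c_nll < nll or np.max(np.abs(c_grad)) < gnorm:
                theta = cand
                break
            t /= 2
        else:
            break
        iterations += 1

    nll, grad, H = _nll_grad_hess(theta, X, logt, d)
    converged = bool(np.max(np.abs(grad)) <= max(gtol, 1e-6))
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p + 1, p + 1), np.nan)
        converged = False

    params = AFTParameters(
        beta=dict(zip(design.column_names, theta[:-1])),
        shape_k=float(np.exp(theta[-1])))
    return FittedAFT(params=params, covariance=cov, loglik=float(-nll),
                     n=design.n, n_events=design.n_events,
                     converged=converged, iterations=iterations)


# --- summary table ------------------------------------------------------

@dataclass
class CoefficientRow:
    term: str
    coef: float
    se: float
    z: Optional[float]
    p: Optional[float]
    ci_low: float
    ci_high: float


@dataclass
class CoefficientTable:
    """Regression summary: one row per coefficient plus a shape row.

    Coefficient rows use Wald statistics (z = coef/se, standard-normal
    p-values, coef +/- z* se intervals).  The shape row's interval is formed
    on the log scale and exponentiated, hence asymmetric about the estimate.
    """

    rows: list[CoefficientRow]
    level: float = 0.95

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_text(self) -> str:
        hdr = f"{'Predictor':<28}{'Coefficient':>12}{'Std Error':>11}" \
              f"{'Z Value':>9}{'p Value':>9}{'Lower CI':>11}{'Upper CI':>11}"
        lines = [hdr]
        for r in self.rows:
            z = f"{r.z:.2f}" if r.z is not None else ""
            p = f"{r.p:.3f}" if r.p is not None else ""
            lines.append(f"{r.term:<28}{r.coef:>12.7g}{r.se:>11.6g}"
                         f"{z:>9}{p:>9}{r.ci_low:>11.6g}{r.ci_high:>11.6g}")
        return "\n".join(lines)


def coefficient_table(fit: FittedAFT, level: float = 0.95) -> CoefficientTable:
    """Build the regression summary table from a converged fit."""
    cov = fit.require_covariance()
    zstar = stats.norm.ppf(0.5 + level / 2)
    se_all = np.sqrt(np.diag(cov))
    rows = []
    for i, name in enumerate(fit.params.column_names):
        b, se = fit.params.beta[name], se_all[i]
        z = b / se if se > 0 else (0.0 if b == 0 else np.inf)
        rows.append(CoefficientRow(
            term=name, coef=b, se=se, z=z, p=float(2 * stats.norm.sf(abs(z))),
            ci_low=b - zstar * se, ci_high=b + zstar * se))
    rows.append(shape_row(fit.params.shape_k, se_all[-1] * fit.params.shape_k, level))
    return CoefficientTable(rows=rows, level=level)


def shape_row(shape_k: float, se_k: float, level: float = 0.95) -> CoefficientRow:
    """Shape summary with a log-scale (asymmetric) confidence interval.

    ``se_k`` is the standard error on the k scale; the interval is
    k * exp(-/+ z* se_k / k), the delta-method image of a symmetric interval
    for log k.
    """
    zstar = stats.norm.ppf(0.5 + level / 2)
    se_log = se_k / shape_k
    return CoefficientRow(term="Shape", coef=shape_k, se=se_k, z=None, p=None,
                          ci_low=shape_k * np.exp(-zstar * se_log),
                          ci_high=shape_k * np.exp(zstar * se_log))


def term_level_tests(fit: FittedAFT, spec) -> list[tuple[str, float, int, float]]:
    """Joint Wald chi-square test per model term.

    Multi-level factors and their interactions are tested jointly across all
    their dummy coefficients: chi2 = b' V^{-1} b with df = number of
    coefficients in the term.
    """
    cov = fit.require_covariance()
    cols = fit.params.column_names
    idx = {c: i for i, c in enumerate(cols)}
    out = []
    for term, term_cols in spec.term_column_map().items():
        ii = [idx[c] for c in term_cols if c in idx]
        if not ii:
            raise ValueError(f"term {term!r} has no coefficients in this fit")
        b = fit.params.beta_vector([cols[i] for i in ii])
        V = cov[np.ix_(ii, ii)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(ii)
        out.append((term, chi2, df, float(stats.chi2.sf(chi2, df))))
    return out


# --- distribution comparison -------------------------------------------

def _family_nll(family: str):
    """Negative log-likelihood builder for alternative AFT error families.

    All families share the AFT structure log T = mu + w/k; they differ in the
    distribution of the standardized residual w = k (log t - mu).
    """
    def nll(theta, X, logt, d, fixed_k=None):
        if fixed_k is None:
            beta, k = theta[:-1], np.exp(theta[-1])
        else:
            beta, k = theta, fixed_k
        w = np.clip(k * (logt - X @ beta), -700, 700)
        if family in ("weibull", "exponential"):
            logf = np.log(k) - logt + w - np.exp(w)
            logS = -np.exp(w)
        elif family == "lognormal":
            logf = stats.norm.logpdf(w) + np.log(k) - logt
            logS = stats.norm.logsf(w)
        elif family == "loglogistic":
            logf = np.log(k) - logt + w - 2 * np.logaddexp(0, w)
            logS = -np.logaddexp(0, w)
        else:
            raise ValueError(f"unknown family {family!r}")
        return -(np.sum(d * logf) + np.sum((1 - d) * logS))
    return nll


def _cumulative_hazard(family, beta, k, X, logt):
    """Cox-Snell residuals: fitted cumulative hazard at each observed time."""
    w = np.clip(k * (logt - X @ beta), -700, 700)
    if family in ("weibull", "exponential"):
        return np.exp(w)
    if family == "lognormal":
        return -stats.norm.logsf(w)
    if family == "loglogistic":
        return np.logaddexp(0, w)
    raise ValueError(family)


def _km_survival(times: np.ndarray, events: np.ndarray):
    """Kaplan-Meier product-limit estimate; returns (event times, S at them)."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e])
    S, s = [], 1.0
    for u in uniq:
        at_risk = np.sum(t >= u)
        d_u = np.sum((t == u) & e)
        s *= 1.0 - d_u / at_risk
        S.append(s)
    return uniq, np.array(S)


def anderson_darling_residuals(resid: np.ndarray, events: np.ndarray) -> float:
    """Anderson-Darling-type discrepancy of censored Cox-Snell residuals
    against the unit exponential.

    The empirical CDF is the Kaplan-Meier estimate of the residual
    distribution (censoring retained); the statistic is the AD-weighted
    squared distance accumulated over the exponential measure between
    consecutive event residuals.
    """
    t_ev, S_km = _km_survival(resid, events.astype(bool))
    if len(t_ev) == 0:
        raise ValueError("no event residuals")
    n = len(resid)
    F0 = 1.0 - np.exp(-t_ev)
    F_km = 1.0 - S_km
    dF0 = np.diff(np.concatenate([[0.0], F0]))
    denom = np.clip(F0 * (1.0 - F0), 1e-12, None)
    return float(n * np.sum((F_km - F0) ** 2 / denom * dF0))


FAMILIES = ("weibull", "exponential", "lognormal", "loglogistic")


@dataclass
class FamilyFit:
    family: str
    ad_statistic: float
    aic: float
    loglik: float
    shape_k: Optional[float]


def compare_distributions(design: DesignMatrix,
                          families: Sequence[str] = FAMILIES) -> list[FamilyFit]:
    """Fit candidate AFT families and rank them by goodness of fit.

    Each family is fitted by maximum likelihood; Cox-Snell residuals are
    scored against the unit exponential with a censoring-adjusted
    Anderson-Darling-type statistic (smaller is better) and the list is
    returned in ascending order of that statistic.  AIC is reported
    alongside.  A family whose fit fails is omitted with a warning.
    """
    _check_design(design)
    X, d = design.X, design.events.astype(float)
    logt = np.log(design.times)
    p = X.shape[1]
    out = []
    for fam in families:
        nll = _family_nll(fam)
        theta0 = np.zeros(p + 1)
        if np.all(X[:, 0] == 1.0):
            theta0[0] = np.log(design.times.sum() / max(d.sum(), 1.0))
        try:
            if fam == "exponential":
                res = scipy.optimize.minimize(
                    lambda th: nll(th, X, logt, d, fixed_k=1.0), theta0[:-1],
                    method="BFGS", options={"gtol": 1e-7, "maxiter": 500})
                beta, k, npar = res.x, 1.0, p
            else:
                res = scipy.optimize.minimize(
                    lambda th: nll(th, X, logt, d), theta0,
                    method="BFGS", options={"gtol": 1e-7, "maxiter": 500})
                beta, k, npar = res.x[:-1], float(np.exp(res.x[-1])), p + 1
            resid = _cumulative_hazard(fam, beta, k, X, logt)
            ad = anderson_darling_residuals(resid, design.events)
            out.append(FamilyFit(family=fam, ad_statistic=ad,
                                 aic=2 * npar + 2 * float(res.fun),
                                 loglik=-float(res.fun),
                                 shape_k=None if fam == "exponential" else k))
        except Exception as e:  # pragma: no cover - defensive
            warnings.warn(f"family {fam!r} failed to fit: {e}")
    return sorted(out, key=lambda f: f.ad_statistic)
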