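"""The bundled reference coefficient set and summaries built from it.

The package ships the published two-center Weibull AFT coefficient set (15
coefficients + shape, with standard errors but no covariance matrix) as its
default calculator model.  Because the covariance was never published,
survival confidence intervals cannot be computed from it — point estimates
and hazard ratios can, and the per-row Wald summary can be rebuilt exactly
from coefficient and standard error.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from . import aft
from .aft import AFTParameters, CoefficientRow, CoefficientTable, FittedAFT
from .design import ModelSpec, default_spec

_FIXTURE = "reference_model.json"


def _load_raw() -> dict:
    text = resources.files("donorcalc.data").joinpath(_FIXTURE).read_text()
    return json.loads(text)


def reference_model() -> FittedAFT:
    """The bundled coefficient-only model (covariance absent)."""
    return FittedAFT.from_dict(_load_raw())


def reference_spec() -> ModelSpec:
    """The model specification the reference coefficients belong to.

    The published set carries no comorbidity coefficients, so predictions
    from it treat comorbidity as the reference class (none).
    """
    return default_spec(include_comorbidity=False)


def reference_standard_errors() -> tuple[dict[str, float], float]:
    """Per-coefficient standard errors and the shape standard error."""
    raw = _load_raw()
    return dict(raw["standard_errors"]), float(raw["shape_standard_error"])


def summary_from_estimates(beta: dict[str, float], ses: dict[str, float],
                           shape_k: Optional[float] = None,
                           shape_se: Optional[float] = None,
                           level: float = 0.95) -> CoefficientTable:
    """Wald summary table from printed coefficients and standard errors.

    Rebuilds z = coef/se, two-sided normal p-values and coef +/- z* se
    intervals; the shape row (when given) uses the log-scale interval.  This
    is how interval columns are derived from a coefficient-only model.
    """
    from scipy import stats
    import numpy as np

    zstar = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for name, b in beta.items():
        se = ses[name]
        z = b / se
        rows.append(CoefficientRow(
            term=name, coef=b, se=se, z=z,
            p=float(2 * stats.norm.sf(abs(z))),
            ci_low=b - zstar * se, ci_high=b + zstar * se))
    if shape_k is not None:
        if shape_se is None:
            raise ValueError("shape_se required when shape_k is given")
        rows.append(aft.shape_row(shape_k, shape_se, level))
    return CoefficientTable(rows=rows, level=level)


def reference_summary(level: float = 0.95) -> CoefficientTable:
    """The full Wald summary of the bundled coefficient set."""
    model = reference_model()
    ses, shape_se = reference_standard_errors()
    return summary_from_estimates(model.params.beta, ses,
                                  model.params.shape_k, shape_se, level)
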