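"""Stabilized inverse-probability-of-exposure weights.

The weight for subject i is

    W_i = P(X = x_i) / P(X = x_i | Z_i)

with the numerator the marginal sample proportion of the subject's own
exposure level and the denominator a fitted logistic regression of exposure
on baseline covariates.  Continuous covariates enter through a natural cubic
spline basis; categorical covariates are dummy-coded against a reference
level.  Weighting standardizes both exposure groups to the covariate
distribution of the pooled sample, so weighted nonparametric curves are
marginal (standardized) curves.

Stabilization keeps the weights centred near 1 — the mean stabilized weight
is 1 in expectation — and an unstabilized variant (numerator 1) is available
via ``stabilized=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .cohort_io import CohortTable

__all__ = [
    "CovariateSpec",
    "WeightModel",
    "SeparationError",
    "PositivityError",
    "fit_stabilized_weights",
    "truncate_weights",
]

logger = logging.getLogger(__name__)

# Clipping floor for fitted probabilities: overflow protection only, not a
# positivity fix.  Probabilities outside [0.01, 0.99] trigger a warning.
_PROB_CLIP = 1e-6
_POSITIVITY_WARN = 0.01


class SeparationError(RuntimeError):
    """The logistic exposure model separated (some coefficients diverge)."""


class PositivityError(RuntimeError):
    """A fitted exposure probability is numerically 0 or 1 for some subjects."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declarative covariate specification for the exposure model.

    ``continuous`` maps covariate name -> spline degrees of freedom (natural
    cubic basis, interior knots at equally spaced quantiles); ``categorical``
    maps covariate name -> reference level (None = first observed level).
    """

    continuous: dict[str, int] = field(default_factory=dict)
    categorical: dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_names(
        cls,
        continuous: list[str] | None = None,
        categorical: list[str] | None = None,
        spline_df: int = 4,
    ) -> "CovariateSpec":
        return cls(
            continuous={c: spline_df for c in (continuous or [])},
            categorical={c: None for c in (categorical or [])},
        )

    @property
    def names(self) -> list[str]:
        return list(self.continuous) + list(self.categorical)

    def formula(self) -> str:
        """patsy right-hand-side formula for the denominator design matrix."""
        terms = []
        for name, df in self.continuous.items():
            terms.append(f"cr({name}, df={int(df)})")
        for name, ref in self.categorical.items():
            if ref is None:
                terms.append(f"C({name})")
            else:
                terms.append(f"C({name}, Treatment(reference={ref!r}))")
        return " + ".join(terms) if terms else "1"


@dataclass
class WeightModel:
    """Fitted stabilized weights plus the exposure model behind them."""

    weights: np.ndarray
    numerator_p1: float
    denominator_probs: np.ndarray  # fitted P(X=1 | Z)
    spec: CovariateSpec
    stabilized: bool
    fit_result: object | None = None
    original_weights: np.ndarray | None = None  # pre-truncation, for audit

    @property
    def diagnostics(self) -> dict[str, float]:
        w = self.weights
        return {
            "n": int(w.size),
            "min": float(w.min()),
            "max": float(w.max()),
            "mean": float(w.mean()),
            "ess": float(w.sum() ** 2 / np.sum(w**2)),
        }


def _design_matrix(cohort: CohortTable, spec: CovariateSpec) -> np.ndarray:
    for name in spec.names:
        if name not in cohort.data.columns:
            raise KeyError(f"covariate {name!r} not in cohort")
    dm = patsy.dmatrix(spec.formula(), cohort.data, return_type="dataframe")
    return np.asarray(dm, dtype=float)


def fit_stabilized_weights(
    cohort: CohortTable,
    spec: CovariateSpec | None = None,
    stabilized: bool = True,
) -> WeightModel:
    """Fit the logistic exposure model and return per-subject weights.

    With an empty covariate specification the denominator equals the
    numerator and every weight is exactly 1 (no model is fitted).
    """
    x = cohort.exposure
    p1 = float(np.mean(x))
    spec = spec or CovariateSpec()

    if not spec.names:
        w = np.ones(cohort.n) if stabilized else np.where(x == 1, 1.0 / p1, 1.0 / (1.0 - p1))
        return WeightModel(w, p1, np.full(cohort.n, p1), spec, stabilized)

    X = _design_matrix(cohort, spec)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(x, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise SeparationError(
            f"logistic exposure model failed ({exc}); check covariates {spec.names}"
        ) from exc
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 50:
        raise SeparationError(
            f"apparent separation in exposure model (|coef| max = "
            f"{np.abs(res.params).max():.1f}); covariates: {spec.names}"
        )
    p_denom1 = np.asarray(res.predict(X), dtype=float)

    extreme = (p_denom1 <= 0.0) | (p_denom1 >= 1.0)
    if extreme.any():
        raise PositivityError(
            f"fitted exposure probability 0 or 1 for subjects "
            f"{np.flatnonzero(extreme)[:10].tolist()}"
        )
    outside = (p_denom1 < _POSITIVITY_WARN) | (p_denom1 > 1 - _POSITIVITY_WARN)
    if outside.any():
        logger.warning(
            "%d subjects with fitted exposure probability outside [%.2f, %.2f]",
            int(outside.sum()), _POSITIVITY_WARN, 1 - _POSITIVITY_WARN,
        )
    p_denom1 = np.clip(p_denom1, _PROB_CLIP, 1 - _PROB_CLIP)

    p_own = np.where(x == 1, p_denom1, 1.0 - p_denom1)
    num = np.where(x == 1, p1, 1.0 - p1) if stabilized else 1.0
    w = num / p_own
    return WeightModel(w, p1, p_denom1, spec, stabilized, fit_result=res)


def truncate_weights(model: WeightModel, lower_pct: float, upper_pct: float) -> WeightModel:
    """Winsorize weights at the given percentiles.

    Percentiles follow the inverse-ECDF (order statistic) rule, so the cut
    points are always observed weights.  Returns a new model; the
    untruncated weights are retained in ``original_weights`` for audit.
    (0, 100) is the identity.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    lo, hi = np.quantile(
        model.weights, [lower_pct / 100.0, upper_pct / 100.0], method="inverted_cdf"
    )
    w = np.clip(model.weights, lo, hi)
    return WeightModel(
        w,
        model.numerator_p1,
        model.denominator_probs,
        model.spec,
        model.stabilized,
        fit_result=model.fit_result,
        original_weights=model.weights.copy(),
    )
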