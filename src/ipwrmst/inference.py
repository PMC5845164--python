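"""Nonparametric bootstrap percentile confidence intervals.

Subjects are resampled with replacement at the subject level (unrestricted
random samples — resampling is not stratified by exposure), and the *whole*
pipeline — weight estimation, curve estimation, integration — is re-run on
every replicate, so the interval reflects the uncertainty in the fitted
weights as well as in the curves.  The CI is the pair of empirical 2.5th and
97.5th percentiles of the replicate estimates (linear-interpolation
quantiles; immaterial at typical replicate counts but fixed for
reproducibility).

Replicates that fail — e.g. logistic separation in a small resample, or an
exposure level absent from the resample — are dropped and counted; more
than 5% failures aborts with a diagnostic.

Determinism: each replicate draws from its own child of a
``numpy.random.SeedSequence`` spawned from the user seed, so results are
bit-identical for a given seed and invariant to how replicates are
scheduled across workers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .cohort_io import CohortTable, ValidationError
from .ipw import PositivityError, SeparationError

__all__ = ["BootstrapResult", "bootstrap_estimate", "make_rmst_estimator"]

logger = logging.getLogger(__name__)

MAX_FAILURE_FRACTION = 0.05

# Failures of these kinds inside a replicate are expected occasionally in
# small resamples and are dropped; anything else propagates as a bug.
_RECOVERABLE = (SeparationError, PositivityError, ValidationError, ValueError, ZeroDivisionError)


@dataclass
class BootstrapResult:
    point_estimate: float
    replicates: np.ndarray
    n_boot: int
    ci: tuple[float, float]
    seed: int
    n_failed: int
    alpha: float = 0.05

    def summary(self) -> dict:
        return {
            "estimate": self.point_estimate,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "seed": self.seed,
        }


def bootstrap_estimate(
    cohort: CohortTable,
    estimator: Callable[[CohortTable], float],
    n_boot: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    n_jobs: int = 1,
) -> BootstrapResult:
    """Percentile-bootstrap CI for any cohort -> scalar estimator.

    ``estimator`` must run the full pipeline from a raw cohort (refitting
    weights internally); the point estimate is the estimator applied to the
    original cohort and does not depend on ``n_boot`` or ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = float(estimator(cohort))

    children = np.random.SeedSequence(seed).spawn(n_boot)

    def one(child) -> float:
        rng = np.random.default_rng(child)
        try:
            return float(estimator(cohort.resample(rng)))
        except _RECOVERABLE:
            return np.nan

    if n_jobs != 1:
        from joblib import Parallel, delayed

        values = Parallel(n_jobs=n_jobs)(delayed(one)(c) for c in children)
        values = np.asarray(values, dtype=float)
    else:
        values = np.array([one(c) for c in children])

    ok = values[~np.isnan(values)]
    n_failed = int(n_boot - ok.size)
    if n_failed > MAX_FAILURE_FRACTION * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap replicates failed "
            "(separation or degenerate resamples); cohort too small or "
            "weights model too rich for bootstrap inference"
        )
    if n_failed:
        logger.warning("dropped %d failed bootstrap replicates", n_failed)
    lo, hi = np.percentile(ok, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(point, ok, n_boot, (float(lo), float(hi)), seed, n_failed, alpha)


def make_rmst_estimator(
    coding,
    horizon: float,
    spec=None,
    estimand: str = "rmst_survival",
    mode: str = "product_limit",
    scale: str = "difference",
) -> Callable[[CohortTable], float]:
    """Estimator closure: refit stabilized weights, contrast exposed vs unexposed.

    This is the pipeline the bootstrap re-runs per replicate.
    """
    from .ipw import fit_stabilized_weights
    from .rmst import group_estimates

    def estimate(cohort: CohortTable) -> float:
        model = fit_stabilized_weights(cohort, spec)
        _, _, contrast = group_estimates(
            cohort, model.weights, coding, horizon, estimand=estimand, mode=mode, scale=scale
        )
        return contrast.value

    return estimate
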