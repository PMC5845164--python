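"""Comparator estimands: pointwise hazard ratios, risk ratio/difference
curves, and a weighted Cox hazard ratio for a binary exposure.

These are the conventional single-time-point measures against which an
RMST contrast is usually read:

* RR(t) = (1 - S1(t)) / (1 - S0(t)) and RD(t) = (1 - S1(t)) - (1 - S0(t))
  from a pair of weighted survival curves;
* pointwise discrete hazard ratios — all-cause, cause-specific
  (d_j/n among the event-free), or subdistribution
  (dF_j(t_k) / (1 - F_j(t_k-)), the hazard that drives the CIF directly);
* a weighted Cox partial-likelihood estimate of the single exposure
  log-hazard ratio with Breslow tie handling.

Points where an estimand is undefined (no risk accrued yet, empty risk set,
zero reference-group hazard) are carried as NaN with a defined-flag — never
interpolated or fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, EventCoding
from .estimators import RiskTable, StepCurve, weighted_cif

__all__ = [
    "EstimandCurve",
    "risk_ratio_curve",
    "risk_difference_curve",
    "pointwise_hazard_ratio_curve",
    "weighted_cox_binary",
    "CoxError",
]


class CoxError(RuntimeError):
    """Weighted Cox fit failed (monotone likelihood or non-convergence)."""


@dataclass
class EstimandCurve:
    times: np.ndarray
    values: np.ndarray  # NaN where undefined
    estimand: str  # hr_pointwise | cs_hr | sd_hr | rr | rd
    null_value: float

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "estimand": self.estimand,
                "value": self.values,
                "defined": self.defined,
            }
        )


def _common_knots(s1: StepCurve, s0: StepCurve) -> np.ndarray:
    end = min(s1.end, s0.end)
    knots = np.union1d(s1.times, s0.times)
    return knots[knots <= end]


def risk_ratio_curve(s1: StepCurve, s0: StepCurve) -> EstimandCurve:
    """RR(t) = (1-S1)/(1-S0) on the union of knots; NaN while the reference
    risk is zero."""
    t = _common_knots(s1, s0)
    r1, r0 = 1.0 - s1(t), 1.0 - s0(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(r0 > 0, r1 / r0, np.nan)
    return EstimandCurve(t, rr, "rr", null_value=1.0)


def risk_difference_curve(s1: StepCurve, s0: StepCurve) -> EstimandCurve:
    """RD(t) = (1-S1) - (1-S0) on the union of knots (always defined)."""
    t = _common_knots(s1, s0)
    rd = (1.0 - s1(t)) - (1.0 - s0(t))
    return EstimandCurve(t, rd, "rd", null_value=0.0)


def _discrete_hazards(risk: RiskTable, times: np.ndarray, event_type, sub: bool) -> np.ndarray:
    """Group hazard at each requested time; NaN where the group has no
    at-risk weight."""
    if sub:
        f = weighted_cif(risk, event_type, mode="product_limit")
        f_at = f(np.minimum(times, f.end))
        idx = np.searchsorted(f.times, times, side="left") - 1
        f_left = f.values[np.maximum(idx, 0)]  # F_j(t-)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = (f_at - f_left) / (1.0 - f_left)
        return np.where(1.0 - f_left > 0, h, np.nan)
    d = risk.d_w if event_type is None else risk.d_w_by_type.get(
        event_type, np.zeros_like(risk.n_w)
    )
    h = np.full(times.shape, np.nan)
    idx = np.searchsorted(risk.times, times)
    inside = (idx < risk.times.size) & np.isclose(
        risk.times[np.minimum(idx, risk.times.size - 1)], times
    )
    at_risk = np.zeros(times.shape, dtype=bool)
    at_risk[inside] = risk.n_w[idx[inside]] > 0
    h[at_risk] = d[idx[at_risk]] / risk.n_w[idx[at_risk]]
    return h


def pointwise_hazard_ratio_curve(
    risk1: RiskTable, risk0: RiskTable, cause="all"
) -> EstimandCurve:
    """Ratio of discrete hazards, exposed over unexposed, at the union of
    the two groups' event times.

    ``cause`` is ``"all"`` (pooled events), an event-type code
    (cause-specific hazard among the event-free), or
    ``("subdistribution", code)`` — the hazard of the CIF increments, whose
    risk set effectively retains subjects after competing events.
    """
    if cause == "all":
        estimand, code, sub = "hr_pointwise", None, False
    elif isinstance(cause, tuple) and cause[0] == "subdistribution":
        estimand, code, sub = "sd_hr", cause[1], True
    else:
        estimand, code, sub = "cs_hr", int(cause), False

    def event_times(r: RiskTable) -> np.ndarray:
        d = r.d_w if code is None else r.d_w_by_type.get(code, np.zeros_like(r.n_w))
        return r.times[d > 0]

    times = np.union1d(event_times(risk1), event_times(risk0))
    h1 = _discrete_hazards(risk1, times, code, sub)
    h0 = _discrete_hazards(risk0, times, code, sub)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((h0 > 0) & ~np.isnan(h1), h1 / h0, np.nan)
    return EstimandCurve(times, ratio, estimand, null_value=1.0)


def weighted_cox_binary(
    cohort: CohortTable,
    weights: np.ndarray | None,
    coding: EventCoding,
    cause: int | str = "all",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Weighted Cox partial-likelihood estimate for a binary exposure.

    Maximizes the Breslow-tie weighted partial likelihood in the single
    exposure coefficient by Newton's method.  ``cause`` selects which
    event code counts as an event (others treated as censored); ``"all"``
    pools every non-censoring code.  Returns (log_hr, hr).
    """
    t = cohort.time
    x = cohort.exposure.astype(float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if cause == "all":
        ev = cohort.event_type != coding.censor_code
    else:
        ev = cohort.event_type == int(cause)
    if not (ev & (x == 1)).any() or not (ev & (x == 0)).any():
        raise CoxError("monotone likelihood: all events in one exposure group")

    # Aggregate per distinct event time: Breslow ties need, at each event
    # time, the weighted event count, the weighted sum of x among events,
    # and the risk-set weighted totals sum(w e^{bx}) and sum(w x e^{bx}).
    order = np.argsort(t, kind="stable")
    ts, xs, ws, evs = t[order], x[order], w[order], ev[order]
    ev_times, inv = np.unique(ts[evs], return_inverse=True)
    d_w = np.zeros(ev_times.size)
    dx_w = np.zeros(ev_times.size)
    np.add.at(d_w, inv, ws[evs])
    np.add.at(dx_w, inv, ws[evs] * xs[evs])
    first_ge = np.searchsorted(ts, ev_times, side="left")
    # suffix sums of w and w*x over the sorted risk sets, split by exposure
    sw1 = np.concatenate([np.cumsum((ws * xs)[::-1])[::-1], [0.0]])[first_ge]
    sw_all = np.concatenate([np.cumsum(ws[::-1])[::-1], [0.0]])[first_ge]
    sw0 = sw_all - sw1  # weighted at-risk total among unexposed

    beta = 0.0
    for _ in range(max_iter):
        e = np.exp(beta)
        denom = sw0 + sw1 * e
        mu = sw1 * e / denom  # weighted mean of x over risk set
        grad = float(np.sum(dx_w - d_w * mu))
        hess = float(-np.sum(d_w * mu * (1.0 - mu)))
        if abs(grad) < tol:
            if abs(beta) > 15:
                raise CoxError("monotone likelihood: log-HR estimate diverges")
            return beta, float(np.exp(beta))
        if hess >= 0:
            raise CoxError("degenerate Hessian in weighted Cox fit")
        step = grad / hess
        beta -= np.clip(step, -5.0, 5.0)
    raise CoxError(f"weighted Cox fit did not converge in {max_iter} iterations")


def weighted_cox_loglik(
    cohort: CohortTable,
    weights: np.ndarray | None,
    coding: EventCoding,
    beta: float,
    cause: int | str = "all",
) -> float:
    """Breslow weighted Cox partial log-likelihood at ``beta`` (for checks)."""
    t = cohort.time
    x = cohort.exposure.astype(float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if cause == "all":
        ev = cohort.event_type != coding.censor_code
    else:
        ev = cohort.event_type == int(cause)
    ll = 0.0
    for i in np.flatnonzero(ev):
        at_risk = t >= t[i]
        ll += w[i] * (beta * x[i] - np.log(np.sum(w[at_risk] * np.exp(beta * x[at_risk]))))
    return float(ll)
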