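"""Weighted nonparametric curve estimation.

Builds weighted risk tables and, from them, right-continuous step curves:
the weighted Kaplan-Meier (product-limit) survival curve and the weighted
cumulative incidence function (CIF) for an event type in the presence of
competing risks,

    F_j(t) = sum_{t_k <= t} S(t_{k-1}) * d_j(t_k) / n(t_k),

where d_j and n are weighted event and at-risk totals and S is the overall
(all-cause) weighted survival.  Two forms of S are supported:

* ``product_limit`` (default): S(t) = prod (1 - d/n).  With this form the
  decomposition F_j + F_comp + S = 1 holds exactly at every knot.
* ``exp_cumhaz``: S(t) = exp(-sum d/n), the Breslow-type exponentiated
  cumulative hazard.  With this form the same sum exceeds 1 whenever any
  event has occurred (1 - h <= exp(-h), strictly for h > 0), so additivity
  is only approximate; the form is provided for completeness.

Ties are resolved by the standard survival convention: at a tied time,
events are removed from the risk set before censorings, i.e. subjects
censored at t are still at risk at t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, EventCoding

__all__ = [
    "RiskTable",
    "StepCurve",
    "build_risk_table",
    "weighted_km",
    "weighted_overall_survival",
    "weighted_cif",
]

MODES = ("product_limit", "exp_cumhaz")


@dataclass
class RiskTable:
    """Weighted risk-set summary at the distinct event times up to a horizon.

    ``times`` are the strictly increasing distinct event times in
    (0, horizon], with the horizon itself appended as a final knot (event
    counts there are 0 unless events occurred exactly at the horizon).
    ``n_w[k]`` is the weighted number at risk just before removals at
    ``times[k]``; ``d_w_by_type[j][k]`` the weighted count of type-j events
    at ``times[k]``; ``c_w[k]`` the weighted censorings in
    [times[k], times[k+1]).
    """

    times: np.ndarray
    n_w: np.ndarray
    d_w_by_type: dict[int, np.ndarray]
    c_w: np.ndarray
    horizon: float
    total_weight: float

    @property
    def d_w(self) -> np.ndarray:
        """Weighted all-cause event count at each time."""
        if not self.d_w_by_type:
            return np.zeros_like(self.n_w)
        return np.sum(list(self.d_w_by_type.values()), axis=0)

    def hazard(self, event_type: int | None = None) -> np.ndarray:
        """Discrete (cause-specific) hazard d_j/n at each knot; 0/0 -> 0."""
        d = self.d_w if event_type is None else self.d_w_by_type.get(event_type)
        if d is None:
            raise KeyError(f"no events of type {event_type} in risk table")
        with np.errstate(invalid="ignore", divide="ignore"):
            h = np.where(d > 0, d / self.n_w, 0.0)
        if np.any(~np.isfinite(h)):
            raise ValueError("events occur where weighted at-risk total is zero")
        return h


@dataclass
class StepCurve:
    """Right-continuous piecewise-constant curve on [0, end].

    ``values[k]`` is the value on [times[k], times[k+1]); times[0] is always
    0 with value 1 (survival) or 0 (CIF).  ``end`` is the support end; the
    curve may not be evaluated or integrated past it.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "survival"  # or "cif"
    end: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times[0] != 0:
            raise ValueError("step curve must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if self.end is None:
            self.end = float(self.times[-1])
        if self.end < self.times[-1]:
            raise ValueError("support end precedes last knot")

    def __call__(self, t):
        """Evaluate the right-continuous curve at times t (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.end):
            raise ValueError("evaluation outside curve support")
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


def build_risk_table(
    cohort: CohortTable,
    weights: np.ndarray | None,
    coding: EventCoding,
    horizon: float,
) -> RiskTable:
    """Aggregate weighted at-risk, event and censoring totals up to ``horizon``.

    The horizon must not exceed the maximum observed follow-up time: the
    curves built from this table are never extrapolated beyond the data.
    """
    t = cohort.time
    j = cohort.event_type
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != t.shape:
        raise ValueError("weights must align with cohort rows")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if horizon > t.max():
        raise ValueError(
            f"horizon {horizon} exceeds maximum observed follow-up {t.max()}; "
            "restricted means are not extrapolated"
        )

    known = {coding.censor_code} | set(coding.event_codes)
    unknown = sorted(int(u) for u in set(np.unique(j)) - known)
    if unknown:
        raise ValueError(f"event codes {unknown} not covered by the event coding")

    is_event = j != coding.censor_code
    ev_times = np.unique(t[is_event & (t <= horizon) & (t > 0)])
    times = np.append(ev_times, horizon) if (ev_times.size == 0 or ev_times[-1] < horizon) else ev_times

    # Risk set at t_k: everyone with follow-up >= t_k (censorings at t_k
    # remain at risk at t_k -> events precede censorings at ties).
    order = np.sort(t)
    w_by_time = w[np.argsort(t, kind="stable")]
    cum_w_from = np.concatenate([np.cumsum(w_by_time[::-1])[::-1], [0.0]])
    first_ge = np.searchsorted(order, times, side="left")
    n_w = cum_w_from[first_ge]

    d_by_type: dict[int, np.ndarray] = {}
    for code in sorted(coding.event_codes):
        mask = j == code
        d = np.zeros_like(times)
        if mask.any():
            idx = np.searchsorted(times, t[mask])
            sel = (idx < times.size) & np.isclose(times[np.minimum(idx, times.size - 1)], t[mask])
            np.add.at(d, idx[sel], w[mask][sel])
        d_by_type[code] = d

    cens = (j == coding.censor_code) & (t <= horizon)
    c_w = np.zeros_like(times)
    if cens.any():
        idx = np.searchsorted(times, t[cens], side="right") - 1
        inside = idx >= 0
        np.add.at(c_w, idx[inside], w[cens][inside])

    return RiskTable(times, n_w, d_by_type, c_w, float(horizon), float(w.sum()))


def _overall_survival_values(risk: RiskTable, mode: str) -> np.ndarray:
    """S at each risk-table knot (no leading t=0 entry)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    h = risk.hazard(None)
    if mode == "product_limit":
        if np.any(h > 1 + 1e-9):
            raise ValueError("discrete hazard exceeds 1; check weights/risk table")
        # summation-order roundoff can leave d/n a few ulp above 1 when the
        # whole risk set fails at once
        return np.cumprod(1.0 - np.minimum(h, 1.0))
    return np.exp(-np.cumsum(h))


def weighted_km(risk: RiskTable) -> StepCurve:
    """Weighted Kaplan-Meier (product-limit) all-cause survival curve."""
    return weighted_overall_survival(risk, mode="product_limit")


def weighted_overall_survival(risk: RiskTable, mode: str = "product_limit") -> StepCurve:
    """Overall weighted survival pooling every event type.

    ``product_limit`` gives prod(1 - d/n); ``exp_cumhaz`` gives
    exp(-sum d/n).
    """
    s = _overall_survival_values(risk, mode)
    times = np.concatenate([[0.0], risk.times])
    values = np.concatenate([[1.0], s])
    return StepCurve(times, values, kind="survival", end=risk.horizon)


def weighted_cif(risk: RiskTable, event_type: int, mode: str = "product_limit") -> StepCurve:
    """Weighted cumulative incidence for one event type (or a composite).

    F_j(t) = sum_{t_k <= t} S(t_{k-1}) d_j(t_k)/n(t_k) with S the overall
    survival in the requested form; F_j(0) = 0.
    """
    if event_type not in risk.d_w_by_type:
        raise KeyError(f"event type {event_type} not present in risk table")
    s = _overall_survival_values(risk, mode)
    s_left = np.concatenate([[1.0], s[:-1]])  # S(t_{k-1})
    h_j = risk.hazard(event_type)
    f = np.cumsum(s_left * h_j)
    times = np.concatenate([[0.0], risk.times])
    values = np.concatenate([[0.0], f])
    return StepCurve(times, values, kind="cif", end=risk.horizon)


def composite_cif(risk: RiskTable, event_types, mode: str = "product_limit") -> StepCurve:
    """CIF for the union of the given event types (sum of their CIFs)."""
    curves = [weighted_cif(risk, c, mode=mode) for c in event_types]
    if not curves:
        times = np.concatenate([[0.0], risk.times])
        return StepCurve(times, np.zeros_like(times), kind="cif", end=risk.horizon)
    values = np.sum([c.values for c in curves], axis=0)
    return StepCurve(curves[0].times, values, kind="cif", end=risk.horizon)
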