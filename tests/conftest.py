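"""Shared fixtures: tiny hand-checkable cohorts and random-cohort factories."""

import numpy as np
import pandas as pd
import pytest

from ipwrmst import CohortTable, EventCoding


def make_cohort(times, events, exposure=None, weights_cols=None, **covariates) -> CohortTable:
    """Build a small cohort table from parallel lists."""
    n = len(times)
    if exposure is None:
        exposure = [0, 1] * (n // 2) + [0] * (n % 2)
    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "exposure": exposure,
            "time": np.asarray(times, dtype=float),
            "event_type": events,
        }
    )
    for name, vals in covariates.items():
        df[name] = vals
    return CohortTable(df, covariate_names=list(covariates))


@pytest.fixture
def four_subject_cohort() -> CohortTable:
    """Events of one type at t=1, 2; censorings at t=3, 4."""
    return make_cohort([1, 2, 3, 4], [1, 1, 0, 0])


@pytest.fixture
def competing_cohort() -> CohortTable:
    """Type-1 event at t=1, type-2 event at t=2, censorings at t=3, 4."""
    return make_cohort([1, 2, 3, 4], [1, 2, 0, 0])


@pytest.fixture
def coding() -> EventCoding:
    return EventCoding(event_of_interest=1)


@pytest.fixture
def competing_coding() -> EventCoding:
    return EventCoding(event_of_interest=1, competing_codes=frozenset({2}))


def random_cohort(
    rng: np.random.Generator,
    n_max: int = 20,
    n_types: int = 2,
    weighted: bool = True,
    with_ties: bool = True,
) -> tuple[CohortTable, np.ndarray]:
    """Random small cohort with ties and mixed event types, plus weights.

    Used by oracle-equivalence and identity property tests; times are drawn
    from a small grid so ties occur often.
    """
    n = int(rng.integers(4, n_max + 1))
    if with_ties:
        times = rng.choice(np.arange(1, 9) / 2.0, size=n)
    else:
        times = rng.uniform(0.1, 4.0, size=n)
    events = rng.integers(0, n_types + 1, size=n)
    exposure = rng.integers(0, 2, size=n)
    if exposure.min() == exposure.max():
        exposure[0] = 1 - exposure[0]
    weights = rng.uniform(0.2, 3.0, size=n) if weighted else np.ones(n)
    return make_cohort(times, events, exposure=exposure), weights


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately loop-based and simple).
# ---------------------------------------------------------------------------


def brute_km(times, events, weights, grid):
    """Product-limit survival by explicit loops: events pooled over types."""
    times = np.asarray(times, float)
    events = np.asarray(events)
    weights = np.asarray(weights, float)
    out = []
    for t in grid:
        s = 1.0
        for tk in sorted(set(times[(events != 0) & (times <= t)])):
            n_at_risk = weights[times >= tk].sum()
            d = weights[(times == tk) & (events != 0)].sum()
            s *= 1.0 - d / n_at_risk
        out.append(s)
    return np.array(out)


def brute_cif(times, events, weights, event_type, grid):
    """Aalen-Johansen style CIF by explicit loops (product-limit overall S)."""
    times = np.asarray(times, float)
    events = np.asarray(events)
    weights = np.asarray(weights, float)
    out = []
    for t in grid:
        f = 0.0
        for tk in sorted(set(times[(events != 0) & (times <= t)])):
            s_left = brute_km(times, events, weights, [tk - 1e-9])[0]  # S(tk-)
            n_at_risk = weights[times >= tk].sum()
            d_j = weights[(times == tk) & (events == event_type)].sum()
            f += s_left * d_j / n_at_risk
        out.append(f)
    return np.array(out)
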