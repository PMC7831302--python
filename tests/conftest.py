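"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nutrispc import CohortConfig, default_config, generate_cohort
from nutrispc.spc import ControlChart


# --- brute-force special-cause oracle ------------------------------------
# Window-scanning reference, deliberately independent of the run-tracking
# detector it checks: a point is flagged under a rule iff it belongs to some
# fixed-length window that satisfies the rule's textbook definition.

def oracle_rule_points(values, centerline, lcl, ucl) -> dict[int, set[int]]:
    v = np.asarray(values, dtype=float)
    c = np.asarray(centerline, dtype=float)
    lcl = np.asarray(lcl, dtype=float)
    ucl = np.asarray(ucl, dtype=float)
    m = len(v)
    out = {1: set(), 2: set(), 3: set(), 4: set()}

    for i in range(m):
        if np.isfinite(v[i]) and np.isfinite(ucl[i]) and (v[i] > ucl[i] or v[i] < lcl[i]):
            out[1].add(i)

    for i in range(m - 8):
        w = range(i, i + 9)
        if all(np.isfinite(v[j]) and np.isfinite(c[j]) for j in w):
            if all(v[j] > c[j] for j in w) or all(v[j] < c[j] for j in w):
                out[2].update(w)

    for i in range(m - 5):
        w = list(range(i, i + 6))
        if all(np.isfinite(v[j]) for j in w):
            if all(v[j + 1] > v[j] for j in w[:-1]) or all(v[j + 1] < v[j] for j in w[:-1]):
                out[3].update(w)

    for i in range(m - 13):
        w = list(range(i, i + 14))
        if all(np.isfinite(v[j]) for j in w):
            d = [v[j + 1] - v[j] for j in w[:-1]]
            if all(x != 0 for x in d) and all(d[k] * d[k + 1] < 0 for k in range(len(d) - 1)):
                out[4].update(w)

    return out


def make_chart(values, centerline=0.0, lcl=None, ucl=None) -> ControlChart:
    """Wrap a raw series in a chart object (constant centerline/limits)."""
    m = len(values)
    values = np.asarray(values, dtype=float)
    cl = np.full(m, centerline, dtype=float)
    ucl_i = np.full(m, np.nan if ucl is None else ucl, dtype=float)
    lcl_i = np.full(m, np.nan if lcl is None else lcl, dtype=float)
    quarters = [str(pd.Period("2014Q1", freq="Q") + i) for i in range(m)]
    return ControlChart(kind="xbar", quarters=quarters, values=values,
                        n=np.ones(m, dtype=int), centerline=float(centerline),
                        centerline_i=cl, ucl_i=ucl_i, lcl_i=lcl_i,
                        baseline_range=None)


def signal_points(signals) -> dict[int, set[int]]:
    out = {1: set(), 2: set(), 3: set(), 4: set()}
    for s in signals:
        out[s.rule].update(s.point_indices)
    return out


def random_rule_sequence(rng: np.random.Generator, max_len: int = 60) -> np.ndarray:
    """Random chart series with ties, centerline hits, gaps, and occasional
    drifts, exercising every rule boundary."""
    m = int(rng.integers(5, max_len + 1))
    v = np.round(rng.normal(0, 1, m), 1)           # ties and exact-0 hits
    if rng.random() < 0.4:                          # inject a monotone drift
        a = int(rng.integers(0, max(m - 7, 1)))
        v[a:a + 7] = np.sort(rng.normal(0, 1, min(7, m - a)))
    if rng.random() < 0.3:                          # inject an alternation
        a = int(rng.integers(0, max(m - 15, 1)))
        k = min(15, m - a)
        v[a:a + k] = np.array([(-1.0) ** j * (1 + 0.1 * j) for j in range(k)])
    if rng.random() < 0.3:                          # gaps
        v[rng.integers(0, m, size=max(1, m // 15))] = np.nan
    return v


# --- fixtures -------------------------------------------------------------

@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (records, roster), shared read-only."""
    cfg = default_config(seed=20141001)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_config():
    """A reduced cohort for tests that iterate over many seeds."""
    return CohortConfig(n_households=60, enrollment_rate=6.0, seed=1)
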