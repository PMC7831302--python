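"""Shewhart control charts with frozen baseline limits and run-rule detection.

Implements the chart suite used in healthcare quality improvement:

* p-chart for a quarterly proportion (variable subgroup sizes, per-point
  3-sigma binomial limits, centerline frozen on a baseline period);
* X-bar and S charts for a quarterly mean/SD (pooled-SD process-sigma
  estimate with the c4 unbiasing constant, per-point limits);
* run charts (median centerline, no control limits);
* the four classic special-cause rules:
    1. one point beyond the 3-sigma limits;
    2. >= 9 consecutive points on one side of the centerline;
    3. >= 6 consecutive points strictly increasing or decreasing;
    4. >= 14 consecutive points alternating up and down.

Baseline parameters are frozen: appending post-baseline points never changes
the centerline or the process-SD estimate. Points with no data (n_i = 0) are
gaps; run-length counters reset across them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "c4", "b3", "b4",
    "ControlChart", "SpecialCauseSignal",
    "p_chart", "xbar_s_chart", "run_chart",
    "detect_special_cause",
]


# --- unbiasing constants --------------------------------------------------

def c4(n: int) -> float:
    """E[s]/sigma for a normal sample of size n:
    c4 = sqrt(2/(n-1)) * Gamma(n/2) / Gamma((n-1)/2). Requires n >= 2."""
    if n < 2:
        raise ValueError("c4 requires subgroup size n >= 2")
    return float(np.sqrt(2.0 / (n - 1)) * np.exp(gammaln(n / 2.0) - gammaln((n - 1) / 2.0)))


def b3(n: int) -> float:
    """Lower S-chart limit factor, max(0, 1 - 3*sqrt(1-c4^2)/c4)."""
    c = c4(n)
    return max(0.0, 1.0 - 3.0 * np.sqrt(1.0 - c * c) / c)


def b4(n: int) -> float:
    """Upper S-chart limit factor, 1 + 3*sqrt(1-c4^2)/c4."""
    c = c4(n)
    return 1.0 + 3.0 * np.sqrt(1.0 - c * c) / c


# --- chart containers -----------------------------------------------------

@dataclass
class ControlChart:
    """A plotted chart: ordered points with per-point limits.

    ``centerline_i`` is the per-point centerline (it varies with subgroup
    size on the S chart; elsewhere it is constant and equals ``centerline``).
    ``ucl_i``/``lcl_i`` are NaN for run charts and for gap points.
    """

    kind: str                               # "p" | "xbar" | "s" | "run"
    quarters: list[str]
    values: np.ndarray
    n: np.ndarray
    centerline: float
    centerline_i: np.ndarray
    ucl_i: np.ndarray
    lcl_i: np.ndarray
    baseline_range: tuple[str, str] | None = None
    sigma_hat: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n = np.asarray(self.n)
        self.centerline_i = np.asarray(self.centerline_i, dtype=float)
        self.ucl_i = np.asarray(self.ucl_i, dtype=float)
        self.lcl_i = np.asarray(self.lcl_i, dtype=float)

    def post_baseline_start(self) -> int:
        """Index of the first point after the baseline range (0 if none)."""
        if self.baseline_range is None:
            return 0
        b_hi = pd.Period(self.baseline_range[1], freq="Q")
        idx = [i for i, q in enumerate(self.quarters) if pd.Period(q, freq="Q") > b_hi]
        return idx[0] if idx else len(self.quarters)

    def to_dict(self) -> dict:
        def _lst(a):
            return [None if not np.isfinite(v) else float(v) for v in a]
        return {
            "kind": self.kind,
            "quarters": list(self.quarters),
            "values": _lst(self.values),
            "n": [int(v) for v in self.n],
            "centerline": None if not np.isfinite(self.centerline) else float(self.centerline),
            "centerline_i": _lst(self.centerline_i),
            "ucl": _lst(self.ucl_i),
            "lcl": _lst(self.lcl_i),
            "baseline_range": list(self.baseline_range) if self.baseline_range else None,
            "sigma_hat": self.sigma_hat,
        }


@dataclass(frozen=True)
class SpecialCauseSignal:
    """A special-cause pattern: rule id 1-4, the contiguous point indices
    involved, and a direction (above/below/up/down/alternating)."""

    rule: int
    point_indices: tuple[int, ...]
    direction: str

    def to_dict(self) -> dict:
        return {"rule": self.rule, "point_indices": list(self.point_indices),
                "direction": self.direction}


# --- chart constructors ---------------------------------------------------

def _baseline_mask(quarters: pd.Series, baseline_range: tuple[str, str]) -> np.ndarray:
    lo = pd.Period(baseline_range[0], freq="Q")
    hi = pd.Period(baseline_range[1], freq="Q")
    periods = [pd.Period(q, freq="Q") for q in quarters]
    return np.array([lo <= p <= hi for p in periods])


def p_chart(summaries: pd.DataFrame, baseline_range: tuple[str, str],
            value_field: str = "prop_stunted", n_field: str = "n") -> ControlChart:
    """Proportion chart with count-weighted frozen baseline centerline.

    P-bar = sum(x_i)/sum(n_i) over baseline quarters; per-point limits
    P-bar +/- 3*sqrt(P-bar*(1-P-bar)/n_i), clipped to [0, 1], with each
    point's own n_i — baseline and post-baseline alike.
    """
    p = summaries[value_field].to_numpy(dtype=float)
    n = summaries[n_field].to_numpy()
    base = _baseline_mask(summaries["quarter"], baseline_range)
    usable = base & (n >= 1) & np.isfinite(p)
    if not usable.any():
        raise ValueError("baseline range contains no usable subgroups")
    pbar = float(np.sum(p[usable] * n[usable]) / np.sum(n[usable]))
    if pbar in (0.0, 1.0):
        warnings.warn("degenerate p-chart centerline (P-bar of 0 or 1); "
                      "limits collapse", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        half = 3.0 * np.sqrt(pbar * (1.0 - pbar) / np.where(n >= 1, n, np.nan))
    ucl = np.clip(pbar + half, 0.0, 1.0)
    lcl = np.clip(pbar - half, 0.0, 1.0)
    gap = ~(n >= 1)
    ucl[gap] = np.nan
    lcl[gap] = np.nan
    return ControlChart(
        kind="p", quarters=list(summaries["quarter"]), values=p, n=n,
        centerline=pbar, centerline_i=np.full(len(p), pbar),
        ucl_i=ucl, lcl_i=lcl, baseline_range=tuple(baseline_range),
    )


def xbar_s_chart(summaries: pd.DataFrame, baseline_range: tuple[str, str],
                 sigma_method: str = "pooled") -> tuple[ControlChart, ControlChart]:
    """X-bar and S charts from quarterly (n_i, mean_i, s_i) subgroups.

    The process SD is estimated from baseline subgroups only and frozen:

    * ``pooled`` (default): sigma_hat = sqrt(sum (n_i-1) s_i^2 / nu) / c4(nu+1)
      with nu = sum(n_i - 1) — preferred with varying subgroup sizes;
    * ``mean-s``: sigma_hat = sum(s_i) / sum(c4(n_i)), the classic
      mean-of-s convention, kept for cross-checks against other software.

    X-bar centerline is the n_i-weighted baseline mean; limits are
    X-bar +/- 3*sigma_hat/sqrt(n_i). The S chart has per-point centerline
    c4(n_i)*sigma_hat and limits b3/b4 times that centerline.
    """
    n = summaries["n"].to_numpy()
    xbar = summaries["mean_laz"].to_numpy(dtype=float)
    s = summaries["sd_laz"].to_numpy(dtype=float)
    base = _baseline_mask(summaries["quarter"], baseline_range)

    small = base & (n < 2)
    if small.any():
        warnings.warn(f"{int(small.sum())} baseline subgroup(s) with n < 2 "
                      "excluded from the process-SD pooling", stacklevel=2)
    use = base & (n >= 2) & np.isfinite(xbar) & np.isfinite(s)
    if not use.any():
        raise ValueError("no baseline subgroups with n >= 2")

    grand_mean = float(np.sum(xbar[use] * n[use]) / np.sum(n[use]))
    if sigma_method == "pooled":
        nu = int(np.sum(n[use] - 1))
        pooled = float(np.sqrt(np.sum((n[use] - 1) * s[use] ** 2) / nu))
        sigma_hat = pooled / c4(nu + 1)
    elif sigma_method == "mean-s":
        sigma_hat = float(np.sum(s[use]) / np.sum([c4(int(k)) for k in n[use]]))
    else:
        raise ValueError(f"unknown sigma_method {sigma_method!r}")
    if sigma_hat == 0.0:
        warnings.warn("process SD estimate is zero; control limits are degenerate",
                      stacklevel=2)

    quarters = list(summaries["quarter"])
    with np.errstate(invalid="ignore", divide="ignore"):
        half = 3.0 * sigma_hat / np.sqrt(np.where(n >= 1, n, np.nan))
    x_ucl = grand_mean + half
    x_lcl = grand_mean - half
    chart_x = ControlChart(
        kind="xbar", quarters=quarters, values=xbar, n=n,
        centerline=grand_mean, centerline_i=np.full(len(xbar), grand_mean),
        ucl_i=x_ucl, lcl_i=x_lcl, baseline_range=tuple(baseline_range),
        sigma_hat=sigma_hat,
    )

    c4_i = np.array([c4(int(k)) if k >= 2 else np.nan for k in n])
    b3_i = np.array([b3(int(k)) if k >= 2 else np.nan for k in n])
    b4_i = np.array([b4(int(k)) if k >= 2 else np.nan for k in n])
    s_center_i = c4_i * sigma_hat
    chart_s = ControlChart(
        kind="s", quarters=quarters, values=s, n=n,
        centerline=float(np.nanmean(s_center_i)) if np.isfinite(s_center_i).any() else np.nan,
        centerline_i=s_center_i,
        ucl_i=b4_i * s_center_i, lcl_i=b3_i * s_center_i,
        baseline_range=tuple(baseline_range), sigma_hat=sigma_hat,
    )
    return chart_x, chart_s


def run_chart(quarters, values, n=None) -> ControlChart:
    """Run chart: median centerline over all plotted (finite) values, no
    control limits. Even counts use the mean-of-middle-two median."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("run chart needs at least one point")
    finite = values[np.isfinite(values)]
    if len(finite) == 0:
        raise ValueError("run chart needs at least one finite value")
    med = float(np.median(finite))
    if n is None:
        n = np.ones(len(values), dtype=int)
    nan = np.full(len(values), np.nan)
    return ControlChart(
        kind="run", quarters=[str(q) for q in quarters], values=values,
        n=np.asarray(n), centerline=med, centerline_i=np.full(len(values), med),
        ucl_i=nan.copy(), lcl_i=nan.copy(), baseline_range=None,
    )


# --- special-cause rules --------------------------------------------------

RULE_MIN_LENGTH = {2: 9, 3: 6, 4: 14}


def _maximal_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) of maximal runs of True (stop exclusive)."""
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def detect_special_cause(chart: ControlChart, scope: str = "post",
                         rules: tuple[int, ...] = (1, 2, 3, 4)) -> list[SpecialCauseSignal]:
    """Detect the four classic run rules on a chart.

    Runs are tracked over the whole series (so a shift that begins in the
    late baseline can complete a run early in the monitoring period), but a
    signal is reported only if it involves at least one post-baseline point
    (``scope="post"``, the default). ``scope="all"`` reports every signal —
    the diagnostic flag-all mode. Gap points (missing values) reset all
    run-length counters; points exactly on the centerline break Rule-2 runs,
    and equal successive values break Rule-3/4 runs.
    """
    if scope not in ("post", "all"):
        raise ValueError("scope must be 'post' or 'all'")
    v = chart.values
    c = chart.centerline_i
    m = len(v)
    first_post = chart.post_baseline_start() if scope == "post" else 0
    signals: list[SpecialCauseSignal] = []

    def _reportable(indices: tuple[int, ...]) -> bool:
        return indices[-1] >= first_post

    ok = np.isfinite(v)

    if 1 in rules and np.isfinite(chart.ucl_i).any():
        for i in range(m):
            if not ok[i] or not np.isfinite(chart.ucl_i[i]):
                continue
            if v[i] > chart.ucl_i[i] or v[i] < chart.lcl_i[i]:
                if _reportable((i,)):
                    signals.append(SpecialCauseSignal(
                        1, (i,), "above" if v[i] > chart.ucl_i[i] else "below"))

    if 2 in rules:
        side = np.where(ok & np.isfinite(c), np.sign(v - c), 0.0)
        for sgn, name in ((1.0, "above"), (-1.0, "below")):
            for a, b_ in _maximal_runs(side == sgn):
                if b_ - a >= RULE_MIN_LENGTH[2]:
                    idx = tuple(range(a, b_))
                    if _reportable(idx):
                        signals.append(SpecialCauseSignal(2, idx, name))

    if 3 in rules or 4 in rules:
        d = np.full(m - 1, np.nan) if m > 1 else np.array([])
        for i in range(m - 1):
            if ok[i] and ok[i + 1]:
                d[i] = v[i + 1] - v[i]

    if 3 in rules and m > 1:
        for sgn, name in ((1.0, "up"), (-1.0, "down")):
            hits = np.isfinite(d) & (np.sign(d) == sgn)
            for a, b_ in _maximal_runs(hits):
                if (b_ - a) + 1 >= RULE_MIN_LENGTH[3]:
                    idx = tuple(range(a, b_ + 1))
                    if _reportable(idx):
                        signals.append(SpecialCauseSignal(3, idx, name))

    if 4 in rules and m > 1:
        # maximal stretches of strictly alternating successive differences
        alt = np.zeros(max(m - 2, 0), dtype=bool)
        for i in range(m - 2):
            alt[i] = (np.isfinite(d[i]) and np.isfinite(d[i + 1])
                      and np.sign(d[i]) * np.sign(d[i + 1]) == -1.0)
        i = 0
        while i < len(alt):
            if not alt[i]:
                i += 1
                continue
            j = i
            while j < len(alt) and alt[j]:
                j += 1
            # diffs i..j inclusive alternate -> points i..j+1 -> length j-i+2
            n_pts = (j - i) + 2
            if n_pts >= RULE_MIN_LENGTH[4]:
                idx = tuple(range(i, i + n_pts))
                if _reportable(idx):
                    signals.append(SpecialCauseSignal(4, idx, "alternating"))
            i = j + 1

    signals.sort(key=lambda s: (s.rule, s.point_indices[0]))
    return signals
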