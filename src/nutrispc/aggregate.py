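"""Reduce visit-level growth-monitoring records to quarterly chart subgroups.

The reduction follows the program's monitoring conventions:

* anthropometry is summarized per calendar quarter (Q1 = Jan-Mar); when a
  child has several measurements in a quarter, the one closest to the
  quarter's midpoint is kept (ties to the earlier visit), so each child
  contributes at most one observation per quarter;
* process indicators (growth monitoring, micronutrient delivery) are
  child-month proportions — the fraction of enrolled children with the flag
  documented in a month — averaged over the quarter's months;
* new-enrollee counts are children whose enrollment date falls in the quarter.

Subgroup SDs use the n-1 (sample) denominator, as the downstream S-chart
convention requires.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "assign_quarter",
    "quarter_midpoint",
    "select_midpoint_observation",
    "deduplicated_observations",
    "quarterly_summaries",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "quarter", "n", "prop_stunted", "mean_laz", "sd_laz",
    "prop_monitored", "prop_micronutrient", "n_new",
]


def assign_quarter(d) -> pd.Period:
    """Calendar quarter of a date (Q1 = Jan-Mar); e.g. 2014-10-01 -> 2014Q4."""
    return pd.Timestamp(d).to_period("Q")


def quarter_midpoint(q: pd.Period | str) -> pd.Timestamp:
    """Midpoint day of a quarter: first day + floor((last - first)/2) days."""
    q = pd.Period(q, freq="Q")
    first = q.start_time.normalize()
    last = q.end_time.normalize()
    return first + pd.Timedelta(days=(last - first).days // 2)


def select_midpoint_observation(visits: pd.DataFrame,
                                quarter: pd.Period | str | None = None):
    """From one child's visits within one quarter, pick the single visit
    closest to the quarter midpoint (ties broken toward the earlier visit).

    Only visits with a usable z-score are considered. Returns the selected
    row as a Series, or None if no visit qualifies.
    """
    usable = visits[pd.to_numeric(visits["laz"], errors="coerce").notna()]
    if len(usable) == 0:
        return None
    dates = pd.to_datetime(usable["visit_date"])
    if quarter is None:
        quarter = assign_quarter(dates.iloc[0])
    mid = quarter_midpoint(quarter)
    dist = (dates - mid).abs()
    order = np.lexsort((dates.to_numpy(), dist.to_numpy()))
    return usable.iloc[order[0]]


def deduplicated_observations(records: pd.DataFrame) -> pd.DataFrame:
    """One anthropometric observation per child per quarter (the midpoint
    rule), as a DataFrame with columns child_id, quarter (string id),
    visit_date, age_months, laz, stunted. This is the panel the GEE
    sensitivity analysis runs on."""
    rec = records[records["laz"].notna()].copy()
    if len(rec) == 0:
        return pd.DataFrame(columns=["child_id", "quarter", "visit_date",
                                     "age_months", "laz", "stunted"])
    rec["visit_date"] = pd.to_datetime(rec["visit_date"])
    vq = rec["visit_date"].dt.to_period("Q")
    mids = vq.map({q: quarter_midpoint(q) for q in vq.unique()})
    rec["_vq"] = vq
    rec["_dist"] = (rec["visit_date"] - mids).abs()
    rec = rec.sort_values(["child_id", "_vq", "_dist", "visit_date"])
    dedup = rec.groupby(["child_id", "_vq"], as_index=False, observed=True).head(1)
    out = dedup[["child_id", "visit_date", "age_months", "laz", "stunted"]].copy()
    out.insert(1, "quarter", dedup["_vq"].astype(str))
    return out.sort_values(["quarter", "child_id"]).reset_index(drop=True)


def _validate(records: pd.DataFrame) -> None:
    hh_per_child = records.groupby("child_id")["household_id"].nunique()
    dupes = hh_per_child[hh_per_child > 1]
    if len(dupes):
        raise ValueError(
            f"child id(s) appear under multiple households: {list(dupes.index[:5])}")
    early = pd.to_datetime(records["visit_date"]) < pd.to_datetime(records["enrollment_date"])
    if early.any():
        raise ValueError(f"{int(early.sum())} visit(s) precede the child's enrollment date")
    ages = pd.to_numeric(records["age_months"])
    if ((ages < 0) | (ages >= 60)).any():
        raise ValueError("age_months outside [0, 60) in visit records")


def _birth_months(records: pd.DataFrame) -> pd.Series:
    """Per-child birth month (Period ordinal), the median implied by
    visit_date minus age_months across that child's rows."""
    vm = pd.Series(pd.PeriodIndex(pd.to_datetime(records["visit_date"]).dt.to_period("M")).asi8,
                   index=records.index)
    implied = vm - pd.to_numeric(records["age_months"]).round().astype(int)
    return implied.groupby(records["child_id"]).median().round().astype(int)


def quarterly_summaries(records: pd.DataFrame,
                        start: str | pd.Period | None = None,
                        end: str | pd.Period | None = None,
                        exit_age_months: int = 60) -> pd.DataFrame:
    """Quarterly chart subgroups from visit-level records.

    Parameters
    ----------
    records : DataFrame in the visit-CSV schema (see synthcohort).
        The plausibility screen is assumed to have been applied already.
    start, end : optional quarter bounds; default spans the earliest
        enrollment/visit quarter through the latest visit quarter. Quarters
        with no eligible children are emitted with n = 0.
    exit_age_months : age at program exit (exclusive), used for the
        process-indicator denominators.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    _validate(records)

    rec = records.copy()
    rec["visit_date"] = pd.to_datetime(rec["visit_date"])
    rec["enrollment_date"] = pd.to_datetime(rec["enrollment_date"])
    rec["_vq"] = rec["visit_date"].dt.to_period("Q")
    rec["_eq"] = rec["enrollment_date"].dt.to_period("Q")

    q_lo = pd.Period(start, freq="Q") if start is not None else min(rec["_vq"].min(), rec["_eq"].min())
    q_hi = pd.Period(end, freq="Q") if end is not None else rec["_vq"].max()
    quarters = pd.period_range(q_lo, q_hi, freq="Q")

    # --- anthropometric subgroups: midpoint deduplication per child-quarter ---
    anthro = rec[rec["laz"].notna()].copy()
    if len(anthro):
        mids = anthro["_vq"].map({q: quarter_midpoint(q) for q in anthro["_vq"].unique()})
        anthro["_dist"] = (anthro["visit_date"] - mids).abs()
        anthro = anthro.sort_values(["child_id", "_vq", "_dist", "visit_date"])
        dedup = anthro.groupby(["child_id", "_vq"], as_index=False, observed=True).head(1)
        grp = dedup.groupby("_vq", observed=True)
        n_i = grp["laz"].size()
        prop = grp["stunted"].mean()
        mean = grp["laz"].mean()
        sd = grp["laz"].std(ddof=1)  # NaN when n < 2
    else:
        n_i = prop = mean = sd = pd.Series(dtype=float)

    # --- process indicators: monthly enrolled denominators ---
    months = pd.period_range(q_lo.asfreq("M", "start"), q_hi.asfreq("M", "end"), freq="M")
    m0 = months[0].ordinal
    n_months = len(months)

    per_child = rec.groupby("child_id").agg(enroll=("enrollment_date", "min"))
    enroll_m = pd.Series(pd.PeriodIndex(per_child["enroll"].dt.to_period("M")).asi8,
                         index=per_child.index)
    birth_m = _birth_months(rec).reindex(per_child.index)
    exit_m = birth_m + exit_age_months  # exclusive

    lo = np.clip(enroll_m.to_numpy() - m0, 0, n_months)
    hi = np.clip(exit_m.to_numpy() - m0, 0, n_months)
    denom = np.zeros(n_months + 1, dtype=int)
    np.add.at(denom, lo[lo < hi], 1)
    np.add.at(denom, hi[lo < hi], -1)
    denom = np.cumsum(denom)[:-1].astype(float)

    rec["_vm"] = pd.PeriodIndex(rec["visit_date"].dt.to_period("M")).asi8 - m0
    in_span = (rec["_vm"] >= 0) & (rec["_vm"] < n_months)

    def _monthly_prop(flag_col: str) -> np.ndarray:
        hits = rec[in_span & (rec[flag_col] == 1)]
        num = np.zeros(n_months)
        counts = hits.groupby("_vm")["child_id"].nunique()
        num[counts.index.to_numpy()] = counts.to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, num / denom, np.nan)

    monthly_mon = _monthly_prop("growth_monitored")
    monthly_mic = _monthly_prop("micronutrient_given")
    month_q = np.array([m.asfreq("Q").ordinal for m in months])

    # --- new enrollees per quarter ---
    new_by_q = per_child["enroll"].dt.to_period("Q").value_counts()

    rows = []
    for q in quarters:
        sel = month_q == q.ordinal
        rows.append({
            "quarter": str(q),
            "n": int(n_i.get(q, 0)),
            "prop_stunted": float(prop.get(q, np.nan)),
            "mean_laz": float(mean.get(q, np.nan)),
            "sd_laz": float(sd.get(q, np.nan)),
            "prop_monitored": float(np.nanmean(monthly_mon[sel])) if np.isfinite(monthly_mon[sel]).any() else np.nan,
            "prop_micronutrient": float(np.nanmean(monthly_mic[sel])) if np.isfinite(monthly_mic[sel]).any() else np.nan,
            "n_new": int(new_by_q.get(q, 0)),
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
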