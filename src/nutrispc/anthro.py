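"""Anthropometric and survey-indicator computations.

Implements the LMS (Box-Cox) z-score transform used by the WHO child growth
standards, the stunting classification, a biological-plausibility screen,
the WHO infant-and-young-child diet-quality indicators (minimum dietary
diversity and minimum meal frequency from a 24-hour recall), and the
Quick-Poverty-Score bracket lookup.

Reference LMS tables are deliberately not bundled; any table following the
CSV schema ``sex,age_months,L,M,S`` is accepted (see :func:`read_lms_table`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LMSRow",
    "DietRecall",
    "lms_zscore",
    "stunting_flag",
    "plausibility_filter",
    "minimum_dietary_diversity",
    "minimum_meal_frequency",
    "poverty_probability",
    "read_lms_table",
    "read_poverty_table",
    "STUNTING_CUTOFF",
    "PLAUSIBILITY_BOUND",
]

#: Z-score below which a child is classified as stunted (strict inequality).
STUNTING_CUTOFF = -2.0

#: Default absolute z bound of the biological-plausibility screen (WHO
#: data-cleaning convention for length/height-for-age).
PLAUSIBILITY_BOUND = 6.0


@dataclass(frozen=True)
class LMSRow:
    """One row of an LMS growth reference: Box-Cox power L, median M,
    coefficient of variation S, indexed by sex and age."""

    L: float
    M: float
    S: float
    sex: str | None = None
    age_months: float | None = None

    def __post_init__(self) -> None:
        if not (self.M > 0):
            raise ValueError(f"LMS median M must be positive, got {self.M}")
        if not (self.S > 0):
            raise ValueError(f"LMS coefficient of variation S must be positive, got {self.S}")


@dataclass(frozen=True)
class DietRecall:
    """A 24-hour dietary recall for one child.

    ``food_groups`` counts distinct food groups (0-7) consumed;
    ``solid_meals`` counts solid/semi-solid meals (milk feeds count for
    non-breastfed infants).
    """

    age_months: float
    breastfed: bool
    food_groups: int
    solid_meals: int

    def __post_init__(self) -> None:
        if self.food_groups < 0 or self.food_groups > 7:
            raise ValueError("food_groups must be in 0..7")
        if self.solid_meals < 0:
            raise ValueError("solid_meals must be non-negative")


def lms_zscore(x: float, row: LMSRow) -> float:
    """Z-score of measurement ``x`` against an LMS reference row.

    Z = ((x/M)**L - 1) / (L*S) for L != 0, and Z = ln(x/M)/S for L = 0.
    """
    if not (x > 0):
        raise ValueError(f"measurement must be positive, got {x}")
    if row.L == 0.0:
        return math.log(x / row.M) / row.S
    return ((x / row.M) ** row.L - 1.0) / (row.L * row.S)


def stunting_flag(z: float | None, cutoff: float = STUNTING_CUTOFF) -> bool | None:
    """True iff z < cutoff (strict). Missing z yields a missing flag (None)."""
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return None
    return bool(z < cutoff)


def plausibility_filter(z: float, bound: float = PLAUSIBILITY_BOUND) -> bool:
    """True (keep) iff |z| <= bound. ``bound=inf`` keeps everything."""
    return bool(abs(z) <= bound)


def minimum_dietary_diversity(r: DietRecall) -> bool | None:
    """WHO minimum dietary diversity: >= 4 distinct food groups in 24 h.

    Defined only for children under 24 months; returns None otherwise.
    """
    if r.age_months >= 24:
        return None
    return r.food_groups >= 4


def minimum_meal_frequency(r: DietRecall) -> bool | None:
    """WHO minimum meal frequency for infants 6-23 months.

    Thresholds: breastfed 6-8 months -> 2 meals; breastfed 9-23 months -> 3;
    non-breastfed 6-23 months -> 4 (milk feeds counting as meals).
    Undefined (None) outside the 6-23 month window.
    """
    if r.age_months < 6 or r.age_months >= 24:
        return None
    if r.breastfed:
        threshold = 2 if r.age_months < 9 else 3
    else:
        threshold = 4
    return r.solid_meals >= threshold


def poverty_probability(raw_score: int, table: list[tuple[int, int, float]]) -> float:
    """Probability (percent) of living below the national poverty line for a
    raw Quick Poverty Score, from a bracket lookup table.

    ``table`` is a list of ``(score_min, score_max, percent)`` with closed
    bounds on both ends; lower scores indicate more poverty, so percents must
    be non-increasing in score.
    """
    if not table:
        raise ValueError("empty poverty lookup table")
    brackets = sorted(table, key=lambda b: b[0])
    for lo, hi, pct in brackets:
        if lo > hi:
            raise ValueError(f"invalid bracket ({lo}, {hi})")
    percents = [b[2] for b in brackets]
    if any(p2 > p1 for p1, p2 in zip(percents, percents[1:])):
        raise ValueError("poverty probabilities must be non-increasing in score")
    for lo, hi, pct in brackets:
        if lo <= raw_score <= hi:
            return float(pct)
    raise ValueError(f"raw score {raw_score} outside table range")


def read_lms_table(path) -> dict[tuple[str, float], LMSRow]:
    """Read an LMS reference CSV (``sex,age_months,L,M,S``) into a lookup
    keyed by (sex, age_months)."""
    df = pd.read_csv(path)
    required = {"sex", "age_months", "L", "M", "S"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LMS table missing columns: {sorted(missing)}")
    out: dict[tuple[str, float], LMSRow] = {}
    for rec in df.itertuples(index=False):
        out[(str(rec.sex), float(rec.age_months))] = LMSRow(
            L=float(rec.L), M=float(rec.M), S=float(rec.S),
            sex=str(rec.sex), age_months=float(rec.age_months),
        )
    return out


def read_poverty_table(path) -> list[tuple[int, int, float]]:
    """Read a poverty lookup CSV with columns
    ``score_min,score_max,percent_below_poverty_line``."""
    df = pd.read_csv(path)
    required = {"score_min", "score_max", "percent_below_poverty_line"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"poverty table missing columns: {sorted(missing)}")
    return [
        (int(r.score_min), int(r.score_max), float(r.percent_below_poverty_line))
        for r in df.itertuples(index=False)
    ]


def apply_plausibility(df: pd.DataFrame, bound: float = PLAUSIBILITY_BOUND,
                       z_col: str = "laz") -> pd.DataFrame:
    """Mask implausible z values (|z| > bound) in a visit table.

    Rows are retained (they still count for enrollment and process
    indicators); only the z value and its derived stunting flag are cleared.
    """
    out = df.copy()
    z = pd.to_numeric(out[z_col], errors="coerce")
    bad = z.abs() > bound
    out.loc[bad, z_col] = np.nan
    if "stunted" in out.columns:
        out.loc[bad, "stunted"] = np.nan
    return out
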