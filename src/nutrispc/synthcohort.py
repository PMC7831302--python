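"""Seeded synthetic visit-level cohorts for a community nutrition program.

Emulates a rolling under-5 cohort with monthly program contacts: children
enter at enrollment (initial door-to-door roster plus Poisson quarterly
recruitment), exit at 60 months of age, and at each monthly contact may have
length/height measured (yielding a length/height-for-age z-score, LAZ) and
micronutrient supplements delivered.

The latent LAZ model is a random-intercept Gaussian:

    Z_it = baseline_mean_laz + b_i + age_slope * age_it + effect(t) + eps_it

with b_i ~ N(0, child_sd^2), eps_it ~ N(0, resid_sd^2), and a step-plus-ramp
intervention effect, effect(t) = min(effect_step + effect_ramp * q, effect_cap)
for quarters q = 0, 1, ... since the intervention start (0 before it).
Stunting is always derived from the latent Z (Z < -2), never simulated
separately, so proportion charts and mean charts stay coherent.

The implied within-child exchangeable correlation is
child_sd^2 / (child_sd^2 + resid_sd^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "config_to_yaml",
    "config_from_yaml",
    "COHORT_COLUMNS",
]

#: Column order of the visit CSV. "NA" encodes missing values; dates are ISO-8601.
COHORT_COLUMNS = [
    "child_id",
    "household_id",
    "visit_date",
    "age_months",
    "laz",
    "stunted",
    "growth_monitored",
    "micronutrient_given",
    "enrollment_date",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study community: ~125 households and ~165 enrolled
    children under five at program start, baseline mean LAZ of -1.77 with a
    marginal baseline stunting probability near 0.42, program span 2014Q4
    through 2019Q4 with the improvement intervention starting 2018Q1.
    """

    n_households: int = 125
    # categorical distribution of under-5 children per household (1..3);
    # mean 1.32 puts the initial roster near 165 children
    children_per_household: dict[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.28, 3: 0.02})
    start_quarter: str = "2014Q4"
    end_quarter: str = "2019Q4"
    enrollment_rate: float = 12.0          # new children per quarter (Poisson mean)
    age_at_entry_max_months: int = 48      # entry ages uniform on [0, this)
    exit_age_months: int = 60
    baseline_mean_laz: float = -1.77
    child_sd: float = 0.95                 # between-child SD (Z units)
    resid_sd: float = 0.55                 # within-child SD (Z units)
    age_slope: float = 0.0                 # Z per month of age (faltering drift)
    intervention_start: str = "2018Q1"
    effect_step: float = 0.10              # Z units at intervention start
    effect_ramp: float = 0.055             # Z units per quarter thereafter
    effect_cap: float = 0.50               # total effect never exceeds this
    visit_prob_pre: float = 0.80           # P(monthly contact) before intervention
    visit_prob_post: float = 0.90
    monitoring_prob_pre: float = 0.60      # P(length measured | contact)
    monitoring_prob_post: float = 0.85
    micronutrient_prob_pre: float = 0.55   # P(supplement delivered | contact)
    micronutrient_prob_post: float = 0.85
    seed: int = 20141001

    def validate(self) -> None:
        probs = [
            self.visit_prob_pre, self.visit_prob_post,
            self.monitoring_prob_pre, self.monitoring_prob_post,
            self.micronutrient_prob_pre, self.micronutrient_prob_post,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not (self.child_sd > 0 and self.resid_sd > 0):
            raise ValueError("child_sd and resid_sd must be positive")
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        if self.enrollment_rate < 0:
            raise ValueError("enrollment_rate must be non-negative")
        if self.exit_age_months <= 0:
            raise ValueError("exit_age_months must be positive")
        if not (0 < self.age_at_entry_max_months <= self.exit_age_months):
            raise ValueError("age_at_entry_max_months must lie in (0, exit_age_months]")
        dist = self.children_per_household
        if not dist or any(k < 1 for k in dist) or any(p < 0 for p in dist.values()):
            raise ValueError("children_per_household must map counts >= 1 to non-negative weights")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError("children_per_household probabilities must sum to 1")
        sq, eq = pd.Period(self.start_quarter, freq="Q"), pd.Period(self.end_quarter, freq="Q")
        iq = pd.Period(self.intervention_start, freq="Q")
        if sq > eq:
            raise ValueError("start_quarter must not be after end_quarter")
        if not (sq <= iq <= eq):
            raise ValueError("intervention_start must lie within [start_quarter, end_quarter]")
        icc = self.icc
        if not (0.0 < icc < 1.0):
            raise ValueError("implied exchangeable correlation must lie in (0, 1)")

    @property
    def icc(self) -> float:
        """Implied within-child exchangeable correlation of repeated Z."""
        v_b, v_e = self.child_sd ** 2, self.resid_sd ** 2
        return v_b / (v_b + v_e)

    @property
    def total_sd(self) -> float:
        """Marginal SD of Z across children, sqrt(child_sd^2 + resid_sd^2)."""
        return float(np.hypot(self.child_sd, self.resid_sd))


def default_config(seed: int = 20141001) -> CohortConfig:
    """Config emulating the study community at its documented scale."""
    cfg = CohortConfig(seed=seed)
    cfg.validate()
    return cfg


def _effect(cfg: CohortConfig, quarters: np.ndarray, q_int: pd.Period) -> np.ndarray:
    """Step-plus-ramp intervention effect for an array of quarter ordinals."""
    q_since = quarters - q_int.ordinal
    eff = cfg.effect_step + cfg.effect_ramp * q_since
    eff = np.minimum(eff, cfg.effect_cap)
    return np.where(q_since >= 0, eff, 0.0)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate visit-level records and the child roster.

    Returns ``(records, roster)``: ``records`` has one row per monthly
    program contact (columns :data:`COHORT_COLUMNS`), ``roster`` one row per
    child ever enrolled. Fully reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    q_start = pd.Period(config.start_quarter, freq="Q")
    q_end = pd.Period(config.end_quarter, freq="Q")
    q_int = pd.Period(config.intervention_start, freq="Q")
    m_start = q_start.asfreq("M", "start")
    m_end = q_end.asfreq("M", "end")

    sizes = np.array(sorted(config.children_per_household), dtype=int)
    size_p = np.array([config.children_per_household[int(k)] for k in sizes], dtype=float)

    # --- roster construction (fixed draw order for reproducibility) ---
    children: list[dict] = []
    hh_counter = 0

    def _new_child(hh_id: str, entry_month: pd.Period) -> None:
        age0 = int(rng.integers(0, config.age_at_entry_max_months))
        day = int(rng.integers(1, 29))
        b_i = rng.normal(0.0, config.child_sd)
        children.append({
            "household_id": hh_id,
            "birth_month": entry_month - age0,
            "enrollment_date": entry_month.start_time + pd.Timedelta(days=day - 1),
            "b_i": b_i,
        })

    # initial door-to-door roster in the first month of the program
    for _ in range(config.n_households):
        hh_counter += 1
        hh_id = f"H{hh_counter:04d}"
        k = int(rng.choice(sizes, p=size_p))
        for _ in range(k):
            _new_child(hh_id, m_start)

    # rolling recruitment: Poisson new children per subsequent quarter,
    # each opening a new household
    for q in pd.period_range(q_start + 1, q_end, freq="Q"):
        n_new = int(rng.poisson(config.enrollment_rate))
        q_months = pd.period_range(q.asfreq("M", "start"), q.asfreq("M", "end"), freq="M")
        for _ in range(n_new):
            hh_counter += 1
            month = q_months[int(rng.integers(0, len(q_months)))]
            _new_child(f"H{hh_counter:04d}", month)

    roster = pd.DataFrame({
        "child_id": [f"C{i + 1:04d}" for i in range(len(children))],
        "household_id": [c["household_id"] for c in children],
        "birth_date": [c["birth_month"].start_time for c in children],
        "enrollment_date": [c["enrollment_date"] for c in children],
    })
    roster["exit_date"] = [
        (c["birth_month"] + config.exit_age_months).start_time for c in children
    ]

    # --- monthly contact simulation per child ---
    frames = []
    for idx, child in enumerate(children):
        child_id = f"C{idx + 1:04d}"
        enroll_month = child["enrollment_date"].to_period("M")
        exit_month = child["birth_month"] + config.exit_age_months  # exclusive
        last = min(m_end, exit_month - 1)
        if enroll_month > last:
            continue
        months = pd.period_range(enroll_month, last, freq="M")
        n = len(months)
        ages = np.array([(m - child["birth_month"]).n for m in months], dtype=int)
        quarters = np.array([m.asfreq("Q").ordinal for m in months], dtype=int)
        post = quarters >= q_int.ordinal

        visit_p = np.where(post, config.visit_prob_post, config.visit_prob_pre)
        visited = rng.random(n) < visit_p
        monitor_p = np.where(post, config.monitoring_prob_post, config.monitoring_prob_pre)
        monitored = (rng.random(n) < monitor_p) & visited
        micro_p = np.where(post, config.micronutrient_prob_post, config.micronutrient_prob_pre)
        micro = (rng.random(n) < micro_p) & visited
        eps = rng.normal(0.0, config.resid_sd, size=n)
        days = rng.integers(1, 29, size=n)

        if not visited.any():
            continue
        z = (config.baseline_mean_laz + child["b_i"]
             + config.age_slope * ages
             + _effect(config, quarters, q_int)
             + eps)
        laz = np.where(monitored, np.round(z, 3), np.nan)

        vdates = pd.PeriodIndex(months).to_timestamp() + pd.to_timedelta(days - 1, unit="D")
        # a first-month contact cannot precede the enrollment day itself
        vdates = pd.DatetimeIndex(
            np.maximum(vdates.to_numpy(), np.datetime64(child["enrollment_date"])))
        frame = pd.DataFrame({
            "child_id": child_id,
            "household_id": child["household_id"],
            "visit_date": vdates[visited],
            "age_months": ages[visited],
            "laz": laz[visited],
            "stunted": np.where(np.isnan(laz[visited]), np.nan,
                                (laz[visited] < -2.0).astype(float)),
            "growth_monitored": monitored[visited].astype(int),
            "micronutrient_given": micro[visited].astype(int),
            "enrollment_date": child["enrollment_date"],
        })
        frames.append(frame)

    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=COHORT_COLUMNS)
        records = records.astype({"age_months": int, "laz": float, "stunted": float,
                                  "growth_monitored": int, "micronutrient_given": int})
    return records[COHORT_COLUMNS], roster


# --- CSV round trip -------------------------------------------------------

def write_cohort(records: pd.DataFrame, path) -> None:
    """Write visit records to CSV (ISO dates, 'NA' for missing values)."""
    out = records.copy()
    missing = set(COHORT_COLUMNS) - set(out.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    for col in ("visit_date", "enrollment_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out["laz"] = out["laz"].map(lambda v: "NA" if pd.isna(v) else f"{v:.3f}")
    out["stunted"] = out["stunted"].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out[COHORT_COLUMNS].to_csv(path, index=False)


def _convert_column(raw: pd.Series, converter, colname: str) -> pd.Series:
    converted, bad_lines = [], []
    for pos, value in enumerate(raw):
        try:
            converted.append(converter(value))
        except (ValueError, TypeError):
            bad_lines.append(pos + 2)  # header is line 1
    if bad_lines:
        raise ValueError(
            f"malformed value(s) in column '{colname}' at line(s) {bad_lines[:10]}")
    return pd.Series(converted, index=raw.index)


def read_cohort(path) -> pd.DataFrame:
    """Read a visit CSV written by :func:`write_cohort` (or real exported data
    in the same schema). Malformed rows are reported with line numbers.

    Rows with LAZ = "NA" are kept — they still count for enrollment and
    process indicators — with ``laz``/``stunted`` set to NaN.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    if len(raw) == 0:
        empty = pd.DataFrame(columns=COHORT_COLUMNS)
        return empty.astype({"age_months": int, "laz": float, "stunted": float,
                             "growth_monitored": int, "micronutrient_given": int,
                             "visit_date": "datetime64[ns]",
                             "enrollment_date": "datetime64[ns]"})

    def _date(v: str):
        ts = pd.Timestamp(v)
        if pd.isna(ts):
            raise ValueError(v)
        return ts

    def _optional_float(v: str) -> float:
        return float("nan") if v == "NA" else float(v)

    def _flag(v: str) -> int:
        iv = int(v)
        if iv not in (0, 1):
            raise ValueError(v)
        return iv

    df = pd.DataFrame({
        "child_id": raw["child_id"],
        "household_id": raw["household_id"],
        "visit_date": _convert_column(raw["visit_date"], _date, "visit_date"),
        "age_months": _convert_column(raw["age_months"], int, "age_months"),
        "laz": _convert_column(raw["laz"], _optional_float, "laz"),
        "stunted": _convert_column(raw["stunted"], _optional_float, "stunted"),
        "growth_monitored": _convert_column(raw["growth_monitored"], _flag, "growth_monitored"),
        "micronutrient_given": _convert_column(raw["micronutrient_given"], _flag, "micronutrient_given"),
        "enrollment_date": _convert_column(raw["enrollment_date"], _date, "enrollment_date"),
    })
    return df[COHORT_COLUMNS]


# --- config (de)serialization --------------------------------------------

def config_to_yaml(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "children_per_household" in data:
        data["children_per_household"] = {
            int(k): float(v) for k, v in data["children_per_household"].items()}
    cfg = CohortConfig(**data)
    cfg.validate()
    return cfg
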