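"""End-to-end analysis: cohort -> quarterly subgroups -> charts -> GEE.

Orchestrates the full monitoring suite of a community nutrition program:
run charts for process indicators (new enrollees, growth monitoring,
micronutrient delivery), a p-chart for stunting prevalence, X-bar and S
charts for the mean length/height-for-age z-score, special-cause detection
against a frozen baseline, a pre/post dot plot of individual z-scores, and
GEE sensitivity analyses (both outcome families, plus a variant excluding
the first quarter).

Every figure's underlying numbers are also written to a versioned
machine-readable results JSON, so no output is figure-only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import anthro, synthcohort
from .aggregate import deduplicated_observations, quarterly_summaries, SUMMARY_COLUMNS
from .gee import build_panel, exclude_first_quarter, fit_gee, marginal_period_effect
from .spc import ControlChart, detect_special_cause, p_chart, run_chart, xbar_s_chart

__all__ = ["AnalysisConfig", "run_pipeline", "RESULTS_SCHEMA_VERSION"]

logger = logging.getLogger("nutrispc")

RESULTS_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    Either ``input_csv`` (a visit CSV in the documented schema) or
    ``cohort`` (a synthetic-cohort config to simulate) must be provided;
    if both are None a default synthetic cohort is generated with ``seed``.
    """

    input_csv: str | None = None
    cohort: synthcohort.CohortConfig | None = None
    baseline_range: tuple[str, str] = ("2014Q4", "2017Q4")
    intervention_start: str = "2018Q1"
    exclude_first_quarter: bool = False
    rules: tuple[int, ...] = (1, 2, 3, 4)
    signal_scope: str = "post"              # flag-all diagnostics via "all"
    sigma_method: str = "pooled"
    plausibility_bound: float = anthro.PLAUSIBILITY_BOUND
    dotplot_quarters: tuple[str, str] = ("2015Q4", "2019Q3")
    process_charts_from_intervention: bool = True
    make_figures: bool = True
    outdir: str = "nutrispc_out"
    seed: int = 20141001

    def validate(self) -> None:
        lo = pd.Period(self.baseline_range[0], freq="Q")
        hi = pd.Period(self.baseline_range[1], freq="Q")
        iv = pd.Period(self.intervention_start, freq="Q")
        if lo > hi:
            raise ValueError("baseline_range start must not be after its end")
        if hi >= iv:
            raise ValueError("baseline_range must precede intervention_start")


def _chart_block(chart: ControlChart, signals) -> dict:
    d = chart.to_dict()
    d["signals"] = [s.to_dict() for s in signals]
    return d


def _fit_block(fit, effect) -> dict:
    d = fit.to_dict()
    d["marginal_effect"] = effect
    return d


def _gee_suite(dedup: pd.DataFrame, intervention_start: str) -> dict:
    out = {}
    for family, outcome in (("binomial", "stunted"), ("gaussian", "laz")):
        panel = build_panel(dedup, intervention_start, outcome=outcome)
        fit = fit_gee(panel, family=family)
        out[family] = _fit_block(fit, marginal_period_effect(fit, panel))
        panel_x = exclude_first_quarter(panel)
        fit_x = fit_gee(panel_x, family=family)
        out[f"{family}_excluding_first_quarter"] = _fit_block(
            fit_x, marginal_period_effect(fit_x, panel_x))
    return out


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the results dict and writes the
    report bundle (summary CSV, results JSON, PNG figures) to
    ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- input ---
    if config.input_csv is not None:
        records = synthcohort.read_cohort(config.input_csv)
        source = {"kind": "csv"}
    else:
        cohort_cfg = config.cohort or synthcohort.default_config(seed=config.seed)
        records, _roster = synthcohort.generate_cohort(cohort_cfg)
        synthcohort.write_cohort(records, outdir / "cohort.csv")
        source = {"kind": "synthetic", "config": asdict(cohort_cfg)}
    logger.info("loaded %d visit records", len(records))
    logger.info("defaults in force: baseline=%s intervention_start=%s "
                "plausibility_bound=%s sigma_method=%s signal_scope=%s "
                "stunting cutoff z < -2 (strict), SD denominator n-1, "
                "quarter-midpoint deduplication with earlier-visit ties",
                config.baseline_range, config.intervention_start,
                config.plausibility_bound, config.sigma_method, config.signal_scope)

    records = anthro.apply_plausibility(records, bound=config.plausibility_bound)

    start_override = None
    if config.exclude_first_quarter:
        vq = pd.to_datetime(records["visit_date"]).dt.to_period("Q")
        first = vq.min()
        records = records[vq != first].reset_index(drop=True)
        start_override = first + 1
        logger.info("sensitivity mode: excluded first quarter %s", first)

    # --- quarterly reduction ---
    summaries = quarterly_summaries(records, start=start_override)
    summaries.to_csv(outdir / "quarterly_summaries.csv", index=False,
                     float_format="%.6g")
    dedup = deduplicated_observations(records)

    # --- charts ---
    quarters = summaries["quarter"]
    iv = pd.Period(config.intervention_start, freq="Q")
    if config.process_charts_from_intervention:
        proc = summaries[[pd.Period(q, freq="Q") >= iv for q in quarters]]
    else:
        proc = summaries

    charts: dict[str, dict] = {}
    rc_enroll = run_chart(quarters, summaries["n_new"], n=summaries["n_new"])
    charts["run_enrollment"] = _chart_block(
        rc_enroll, detect_special_cause(rc_enroll, scope="all",
                                        rules=tuple(r for r in config.rules if r != 1)))
    for name, col in (("run_monitoring", "prop_monitored"),
                      ("run_micronutrient", "prop_micronutrient")):
        rc = run_chart(proc["quarter"], proc[col])
        charts[name] = _chart_block(
            rc, detect_special_cause(rc, scope="all",
                                     rules=tuple(r for r in config.rules if r != 1)))

    pch = p_chart(summaries, config.baseline_range)
    charts["p_stunted"] = _chart_block(
        pch, detect_special_cause(pch, scope=config.signal_scope, rules=config.rules))
    xch, sch = xbar_s_chart(summaries, config.baseline_range,
                            sigma_method=config.sigma_method)
    charts["xbar_laz"] = _chart_block(
        xch, detect_special_cause(xch, scope=config.signal_scope, rules=config.rules))
    charts["s_laz"] = _chart_block(
        sch, detect_special_cause(sch, scope=config.signal_scope, rules=config.rules))

    # --- pre/post dot plot data ---
    dot = {}
    for label, q in zip(("pre", "post"), config.dotplot_quarters):
        sub = dedup[dedup["quarter"] == q]
        dot[label] = {"quarter": q,
                      "laz": [float(v) for v in sub["laz"]],
                      "stunted": [bool(v) for v in sub["stunted"]]}

    # --- GEE sensitivity analysis ---
    gee_results = _gee_suite(dedup, config.intervention_start)

    results = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "settings": {
            "source": source,
            "baseline_range": list(config.baseline_range),
            "intervention_start": config.intervention_start,
            "exclude_first_quarter": config.exclude_first_quarter,
            "rules": list(config.rules),
            "signal_scope": config.signal_scope,
            "sigma_method": config.sigma_method,
            "plausibility_bound": config.plausibility_bound,
            "dotplot_quarters": list(config.dotplot_quarters),
            "seed": config.seed,
        },
        "quarterly_summaries": {
            col: [None if (isinstance(v, float) and not np.isfinite(v)) else v
                  for v in summaries[col]]
            for col in SUMMARY_COLUMNS
        },
        "charts": charts,
        "dotplot": dot,
        "gee": gee_results,
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)

    if config.make_figures:
        _render_figures(results, outdir, config)
    return results


# --- figure rendering -----------------------------------------------------

def _render_figures(results: dict, outdir: Path, config: AnalysisConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    iv = config.intervention_start
    for name, block in results["charts"].items():
        fig, ax = plt.subplots(figsize=(8, 4))
        q = block["quarters"]
        x = np.arange(len(q))
        vals = np.array([np.nan if v is None else v for v in block["values"]])
        ax.plot(x, vals, "o-", color="tab:blue", ms=4)
        cl = np.array([np.nan if v is None else v for v in block["centerline_i"]])
        style = "--" if block["kind"] == "run" else "-"
        label = "median" if block["kind"] == "run" else "centerline"
        ax.plot(x, cl, style, color="tab:gray", label=label)
        if block["kind"] != "run":
            for lim, nm in (("ucl", "UCL"), ("lcl", "LCL")):
                arr = np.array([np.nan if v is None else v for v in block[lim]])
                ax.plot(x, arr, ":", color="tab:red")
                if np.isfinite(arr).any():
                    j = int(np.flatnonzero(np.isfinite(arr))[-1])
                    ax.annotate(nm, (x[j], arr[j]), fontsize=8, color="tab:red")
        rule1 = {i for s in block["signals"] if s["rule"] == 1 for i in s["point_indices"]}
        if rule1:
            idx = sorted(rule1)
            ax.plot(x[idx], vals[idx], "o", color="red", ms=6)
        if iv in q:
            xi = q.index(iv)
            ax.axvline(xi, color="black", lw=0.8, ls=":")
            ax.annotate("intervention", (xi, ax.get_ylim()[1]), fontsize=7,
                        ha="left", va="top",
                        arrowprops=None, xytext=(xi + 0.2, ax.get_ylim()[1]))
        step = max(1, len(q) // 12)
        ax.set_xticks(x[::step])
        ax.set_xticklabels(q[::step], rotation=45, fontsize=7)
        ax.set_title(name.replace("_", " "))
        ax.legend(loc="best", fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / f"fig_{name}.png", dpi=100)
        plt.close(fig)

    # pre/post dot plot of individual z-scores
    dot = results["dotplot"]
    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for k, (label, block) in enumerate(dot.items()):
        laz = np.asarray(block["laz"])
        stunted = np.asarray(block["stunted"], dtype=bool)
        xj = k + rng.uniform(-0.12, 0.12, size=len(laz))
        ax.scatter(xj[~stunted], laz[~stunted], s=12, color="tab:red", label=None)
        ax.scatter(xj[stunted], laz[stunted], s=12, color="tab:blue", label=None)
    ax.axhline(-2.0, color="gray", ls="--", lw=0.8)
    ax.set_xticks([0, 1])
    ax.set_xticklabels([f"{lb} ({bl['quarter']})" for lb, bl in dot.items()])
    ax.set_ylabel("length/height-for-age Z")
    fig.tight_layout()
    fig.savefig(outdir / "fig_dotplot.png", dpi=100)
    plt.close(fig)
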