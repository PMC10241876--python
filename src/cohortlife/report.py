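"""Report assembly: run the full pipeline and render its outputs.

``run_analysis`` orchestrates exclusion -> schedules -> parameters ->
jackknife -> treatment comparison -> stage summaries, returning an
:class:`AnalysisReport` whose raw fields hold every number at full
precision; rendering (``render_tables``) is formatting only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .jackknife import PARAMETERS, JackknifeEstimate, TukeyComparison, compare_treatments, jackknife_parameters
from .records import CohortStudy, apply_exclusions, validate_cohort
from .schedules import Schedule, build_schedule, export_schedule
from .stage_stats import GroupSummary, reproductive_summary, stage_duration_summary

__all__ = [
    "AnalysisReport",
    "run_analysis",
    "render_tables",
    "plot_schedules",
    "format_cell",
    "parse_cell",
    "report_to_json",
]

log = logging.getLogger("cohortlife")


@dataclass
class AnalysisReport:
    schedules: dict[str, Schedule]
    jackknife: dict[str, dict[str, JackknifeEstimate]]   # treatment -> param -> est
    comparisons: dict[str, TukeyComparison]              # param -> comparison
    stage_summaries: list[GroupSummary]
    reproductive_summaries: list[GroupSummary]
    provenance: dict = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)


def run_analysis(
    cohorts: Sequence[CohortStudy],
    age_origin: str = "egg",
    jackknife_unit: str = "individual",
    alpha: float = 0.05,
) -> AnalysisReport:
    """Deterministic end-to-end analysis of one or more cohorts."""
    notices: list[str] = []
    clean: list[CohortStudy] = []
    for cohort in cohorts:
        excluded = apply_exclusions(cohort)
        n_lost = len(cohort) - len(excluded)
        log.info("exclusions treatment=%s in=%d lost=%d out=%d",
                 cohort.treatment, len(cohort), n_lost, len(excluded))
        if not excluded.individuals:
            raise ValueError(f"treatment {cohort.treatment!r}: empty cohort after exclusions")
        report = validate_cohort(excluded)
        if not report.ok:
            raise ValueError(
                f"treatment {cohort.treatment!r}: invalid cohort: {report.violations[:3]}"
            )
        clean.append(excluded)

    schedules: dict[str, Schedule] = {}
    jack: dict[str, dict[str, JackknifeEstimate]] = {}
    for cohort in clean:
        schedule = build_schedule(cohort, age_origin)
        schedules[cohort.treatment] = schedule
        log.info("schedule treatment=%s ages=%d surv=%.4f sr=%.4f nf=%d",
                 cohort.treatment, len(schedule), schedule.surv, schedule.sr, schedule.nf)
        try:
            jack[cohort.treatment] = jackknife_parameters(
                cohort, unit=jackknife_unit, age_origin=age_origin)
        except ValueError as exc:
            notices.append(f"{cohort.treatment}: jackknife skipped ({exc})")
            jack[cohort.treatment] = {}
        log.info("jackknife treatment=%s params=%s", cohort.treatment,
                 sorted(jack[cohort.treatment]))

    comparisons: dict[str, TukeyComparison] = {}
    for parameter in PARAMETERS:
        ests = [jack[t][parameter] for t in jack if parameter in jack[t]]
        if len(ests) >= 2:
            try:
                comparisons[parameter] = compare_treatments(ests, alpha=alpha)
            except ValueError as exc:
                notices.append(f"{parameter}: comparison skipped ({exc})")
        else:
            notices.append(f"{parameter}: comparison skipped (< 2 treatments)")

    stage = stage_duration_summary(clean, alpha=alpha)
    repro = reproductive_summary(clean, alpha=alpha)
    log.info("summaries stages=%d reproductive=%d", len(stage), len(repro))

    provenance = {
        "software": f"cohortlife {__version__}",
        "age_origin": age_origin,
        "jackknife_unit": jackknife_unit,
        "alpha": alpha,
        "treatments": [c.treatment for c in clean],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return AnalysisReport(
        schedules=schedules, jackknife=jack, comparisons=comparisons,
        stage_summaries=stage, reproductive_summaries=repro,
        provenance=provenance, notices=notices,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def format_cell(value: float, se: float | None = None, letter: str = "",
                nd_value: int = 3, nd_se: int = 4) -> str:
    """Render ``estimate ± SE`` with an optional trailing letter."""
    if not np.isfinite(value):
        return ""
    cell = f"{value:.{nd_value}f}"
    if se is not None and np.isfinite(se):
        cell += f" ± {se:.{nd_se}f}"
    return cell + letter


def parse_cell(cell: str) -> tuple[float, float | None, str]:
    """Inverse of :func:`format_cell` (value, se, letter)."""
    cell = cell.strip()
    if not cell:
        return float("nan"), None, ""
    letter = ""
    while cell and cell[-1].isalpha():
        letter = cell[-1] + letter
        cell = cell[:-1]
    if "±" in cell:
        v, s = cell.split("±")
        return float(v), float(s), letter
    return float(cell), None, letter


def _param_letter(report: AnalysisReport, parameter: str, treatment: str) -> str:
    comp = report.comparisons.get(parameter)
    if comp is None or treatment not in comp.treatments:
        return ""
    return comp.letters[comp.treatments.index(treatment)]


def render_tables(report: AnalysisReport) -> dict[str, pd.DataFrame]:
    """Three tables: demographic parameters, stage durations, reproduction.

    Rounding follows the familiar presentation: durations to 1 d.p.,
    R0/T/rm/lambda to 3 d.p. with 4 d.p. standard errors.
    """
    rows = []
    for treatment, ests in report.jackknife.items():
        row: dict[str, str] = {"treatment": treatment}
        for parameter in PARAMETERS:
            est = ests.get(parameter)
            row[parameter] = "" if est is None else format_cell(
                est.theta_jack, est.se, _param_letter(report, parameter, treatment))
        rows.append(row)
    params_df = pd.DataFrame(rows, columns=["treatment", *PARAMETERS])

    def summary_frame(summaries: list[GroupSummary], nd: int = 1) -> pd.DataFrame:
        if not summaries:
            return pd.DataFrame()
        treatments = summaries[0].treatments
        out = []
        for t in treatments:
            row = {"treatment": t}
            for s in summaries:
                i = s.treatments.index(t)
                cell = format_cell(s.means[i], s.ses[i], s.letter_for(t),
                                   nd_value=nd, nd_se=2)
                row[s.variable] = f"{cell} ({s.ns[i]})" if cell else ""
            out.append(row)
        return pd.DataFrame(out)

    return {
        "params": params_df,
        "stages": summary_frame(report.stage_summaries),
        "reproduction": summary_frame(report.reproductive_summaries),
    }


def plot_schedules(schedules: dict[str, Schedule], out_dir: str | Path) -> dict[str, Path]:
    """Per-treatment l_x/m_x panels (PNG) plus one combined CSV.

    The CSV carries every plotted number, so tests never inspect pixels.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    frames = []
    for treatment, schedule in schedules.items():
        rows = export_schedule(schedule)
        frames.append(pd.DataFrame(rows, columns=["x", "lx", "mx"]).assign(treatment=treatment))
    csv_path = out_dir / "schedules.csv"
    pd.concat(frames, ignore_index=True)[["treatment", "x", "lx", "mx"]].to_csv(
        csv_path, index=False)
    written["csv"] = csv_path

    n = len(schedules)
    fig, axes = plt.subplots(n, 1, figsize=(7, 2.6 * n), squeeze=False, sharex=True)
    for ax, (treatment, schedule) in zip(axes[:, 0], schedules.items()):
        ax.step(schedule.ages, schedule.lx, where="post", color="tab:blue", label="$l_x$")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("$l_x$", color="tab:blue")
        twin = ax.twinx()
        twin.plot(schedule.ages, schedule.mx, color="tab:red", label="$m_x$")
        twin.set_ylabel("$m_x$", color="tab:red")
        ax.set_title(treatment)
    axes[-1, 0].set_xlabel(f"age (days, origin={next(iter(schedules.values())).age_origin})")
    fig.tight_layout()
    png_path = out_dir / "schedules.png"
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    written["png"] = png_path
    return written


# ---------------------------------------------------------------------------
# machine-readable bundle
# ---------------------------------------------------------------------------

def report_to_json(report: AnalysisReport) -> dict:
    """Full-precision machine-readable bundle."""

    def est_dict(e: JackknifeEstimate) -> dict:
        return {
            "theta_all": e.theta_all,
            "theta_jack": e.theta_jack,
            "se": e.se,
            "n_units": e.n_units,
            "pseudo_values": e.pseudo_values.tolist(),
            "warnings": e.warnings,
        }

    def comp_dict(c: TukeyComparison) -> dict:
        return {
            "treatments": c.treatments,
            "means": c.means.tolist(),
            "ns": c.ns.tolist(),
            "mse": c.mse,
            "df": c.df,
            "pvalues": c.pvalues.tolist(),
            "letters": c.letters,
            "alpha": c.alpha,
        }

    def summary_dict(s: GroupSummary) -> dict:
        out = {
            "variable": s.variable,
            "treatments": s.treatments,
            "means": s.means,
            "ses": s.ses,
            "ns": s.ns,
        }
        if s.test is not None:
            out["test"] = {
                "method": s.test.method,
                "statistic": s.test.statistic,
                "df": list(s.test.df),
                "pvalue": s.test.pvalue,
                "letters": s.test.letters,
                "tested_treatments": s.tested_treatments,
            }
        return out

    bundle = {
        "provenance": report.provenance,
        "schedules": {
            t: {"ages": s.ages.tolist(), "lx": s.lx.tolist(), "mx": s.mx.tolist(),
                "age_origin": s.age_origin, "surv": s.surv, "sr": s.sr, "nf": s.nf}
            for t, s in report.schedules.items()
        },
        "parameters": {
            t: {p: est_dict(e) for p, e in ests.items()}
            for t, ests in report.jackknife.items()
        },
        "comparisons": {p: comp_dict(c) for p, c in report.comparisons.items()},
        "stage_summaries": [summary_dict(s) for s in report.stage_summaries],
        "reproductive_summaries": [summary_dict(s) for s in report.reproductive_summaries],
        "notices": report.notices,
    }
    digest = hashlib.sha256(
        json.dumps(bundle, sort_keys=True, default=str).encode()).hexdigest()
    bundle["provenance"]["content_hash"] = digest
    return bundle
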