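"""Fit-report serialization: a JSON document sufficient to reproduce the fit
and a human-readable table (per parameter: best-fit / CI / dependency, then
per-dataset and global goodness of fit)."""

from __future__ import annotations

import json

import numpy as np

from .diagnostics import DiagnosticsReport, IntervalEstimate
from .fitting import FitResult
from .plan import plan_to_dict

__all__ = ["write_report", "read_report", "report_to_dict", "format_report_text"]

OPEN_END = "?"


def _ci_doc(ci: IntervalEstimate) -> dict:
    return {
        "lower": OPEN_END if ci.open_lower else ci.lower,
        "upper": OPEN_END if ci.open_upper else ci.upper,
        "level": ci.level,
    }


def report_to_dict(fit: FitResult, report: DiagnosticsReport) -> dict:
    doc = {
        "parameters": {
            name: {
                "best_fit": fit.values[name],
                "se": fit.se[name],
                "ci": _ci_doc(report.ci[name]) if name in report.ci else None,
                "dependency": report.dependency.get(name),
                "ambiguous": report.ambiguous.get(name, False),
                "dependency_note": report.high_dependency.get(name, ""),
            }
            for name in fit.names
        },
        "r2_individual": report.r2_individual,
        "r2_global": report.r2_global,
        "r2_adjusted": report.r2_adjusted,
        "ssr": fit.ssr,
        "n_points": fit.n_points,
        "k_free": fit.k_free,
        "dof": fit.dof,
        "converged": fit.converged,
        "rank_deficient": fit.rank_deficient,
        "ambiguous_fit": report.ambiguous_fit,
        "ci_level": report.level,
        "plan": plan_to_dict(fit.plan) if fit.plan is not None else None,
        "options": {
            "max_iterations": fit.options.max_iterations,
            "tolerance": fit.options.tolerance,
            "multistart": fit.options.multistart,
            "seed": fit.options.seed,
            "use_means": fit.options.use_means,
        },
        "init": fit.init,
    }
    return doc


def write_report(fit: FitResult, report: DiagnosticsReport, path) -> None:
    """Write the JSON report; everything needed to re-run the fit is included."""
    with open(path, "w") as fh:
        json.dump(report_to_dict(fit, report), fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def format_report_text(fit: FitResult, report: DiagnosticsReport) -> str:
    """Plain-text table: best-fit (top), CI (middle, open ends as '?'),
    dependency (bottom) per free parameter, then the R² block."""
    lines = []
    lines.append(f"{'parameter':<14}{'best-fit':>12}  {'95% CI':<26}{'dependency':>11}")
    for name in fit.names:
        ci = report.ci.get(name)
        ci_txt = str(ci) if ci is not None else "-"
        dep = report.dependency.get(name)
        dep_txt = f"{dep:.4f}" if dep is not None else "-"
        flag = "  [ambiguous]" if report.ambiguous.get(name) else ""
        note = report.high_dependency.get(name, "")
        note_txt = f"  ({note})" if note else ""
        lines.append(
            f"{name:<14}{fit.values[name]:>12.4g}  {ci_txt:<26}{dep_txt:>11}{flag}{note_txt}"
        )
    lines.append("")
    for label in sorted(report.r2_individual):
        r2 = report.r2_individual[label]
        lines.append(f"R2 {label:<16}" + (f"{r2:.4f}" if r2 is not None else "undefined"))
    if report.r2_global is not None:
        lines.append(f"Global R2        {report.r2_global:.4f}")
    if report.r2_adjusted is not None:
        lines.append(f"Adjusted R2      {report.r2_adjusted:.4f}")
    lines.append(f"N = {fit.n_points}, K = {fit.k_free}, dof = {fit.dof}")
    lines.append(f"converged: {fit.converged}")
    if report.ambiguous_fit:
        lines.append("fit is AMBIGUOUS (redundant parameter present)")
    return "\n".join(lines) + "\n"
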