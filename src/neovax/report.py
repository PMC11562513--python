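"""Cohort-level summary report.

Aggregates vaccine-design, immune-monitoring and outcome results into one
report: epitopes-per-vaccine statistics, responder and immunogenic-epitope
fractions, ICS positive counts under the strict and relaxed rules, recurrence
count, and the Kaplan-Meier RFS estimate at a requested horizon.  The
published per-patient trial summary (epitope counts, immune response,
recurrence) ships as packaged data and can be summarized with the same code
path.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import survival as surv


def load_trial_summary() -> pd.DataFrame:
    """Published per-patient summary: patient_id, n_epitopes (epitopes in
    vaccine), immune_response (Y/N), recurrence (Y/N)."""
    with resources.files("neovax.data").joinpath("trial_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def epitope_count_stats(counts) -> dict[str, float]:
    """median / mean / min / max / total of epitopes-per-vaccine counts."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        return {k: math.nan for k in ("median", "mean", "min", "max", "total", "n")}
    return {"median": float(np.median(arr)), "mean": float(arr.mean()),
            "min": float(arr.min()), "max": float(arr.max()),
            "total": float(arr.sum()), "n": int(arr.size)}


def trial_summary_report() -> dict[str, Any]:
    """Cohort statistics recomputed from the packaged published summary."""
    tab = load_trial_summary()
    stats = epitope_count_stats(tab["n_epitopes"])
    return {
        "n_vaccinated": int(len(tab)),
        "epitopes_per_vaccine": stats,
        "responders": int((tab["immune_response"] == "Y").sum()),
        "recurrences": int((tab["recurrence"] == "Y").sum()),
    }


def cohort_report(selections: Mapping[str, Any] | None = None,
                  responder_summary: pd.DataFrame | None = None,
                  ics_calls: pd.DataFrame | None = None,
                  followup: pd.DataFrame | None = None,
                  horizon_months: float = 36.0) -> dict[str, Any]:
    """Assemble the cohort report from whichever stages were run.

    ``selections`` maps patient -> VaccineSelection (or an epitope count);
    ``responder_summary`` is classify_responder output; ``ics_calls`` carries
    ics_positive_strict / ics_positive_relaxed columns; ``followup`` is the
    tidy survival table.  Absent inputs yield undefined (NaN / None) entries;
    an empty cohort is reported as n=0 with undefined statistics."""
    report: dict[str, Any] = {"n_vaccinated": 0}
    if selections is not None:
        counts = [getattr(s, "n_selected", s) for s in selections.values()]
        report["n_vaccinated"] = len(counts)
        report["epitopes_per_vaccine"] = epitope_count_stats(counts)
    if responder_summary is not None and len(responder_summary):
        n = int(len(responder_summary))
        n_resp = int(responder_summary["responder"].sum())
        n_epi = int(responder_summary["n_neoantigens"].sum())
        n_conf = int(responder_summary["n_confirmed"].sum())
        report["n_vaccinated"] = max(report["n_vaccinated"], n)
        report["responders"] = n_resp
        report["responder_fraction"] = n_resp / n
        report["immunogenic_epitopes"] = n_conf
        report["immunogenic_fraction"] = n_conf / n_epi if n_epi else math.nan
    if ics_calls is not None and len(ics_calls):
        per_neo = ics_calls.groupby(["patient", "neoantigen"])[
            ["ics_positive_strict", "ics_positive_relaxed"]].any()
        report["ics_positive_strict"] = int(per_neo["ics_positive_strict"].sum())
        report["ics_positive_relaxed"] = int(per_neo["ics_positive_relaxed"].sum())
    if followup is not None and len(followup):
        vacc = followup[followup["arm"] == surv.VACCINATED]
        report["recurrences"] = int(vacc["event"].astype(bool).sum())
        try:
            cmp = surv.compare_arms(followup, horizon_months)
            report["rfs"] = {
                "horizon_months": horizon_months,
                "vaccinated": cmp.rfs_vaccinated,
                "vaccinated_ci": list(cmp.rfs_vaccinated_ci),
                "control": cmp.rfs_control,
                "control_ci": list(cmp.rfs_control_ci),
                "logrank_chi2": cmp.logrank_chi2,
                "logrank_p": cmp.logrank_p,
            }
        except ValueError:
            km = surv.km_estimate(vacc["time_months"], vacc["event"].astype(bool))
            s, lo, hi = surv.km_interval_at(km, horizon_months)
            report["rfs"] = {"horizon_months": horizon_months, "vaccinated": s,
                             "vaccinated_ci": [lo, hi]}
    return report


def report_to_markdown(report: Mapping[str, Any]) -> str:
    """Human-readable rendering of a cohort report."""
    lines = ["# Cohort report", "",
             f"- Patients vaccinated: {report.get('n_vaccinated', 0)}"]
    epi = report.get("epitopes_per_vaccine")
    if epi:
        lines.append(
            f"- Epitopes per vaccine: median {epi['median']:g} "
            f"(range {epi['min']:g}-{epi['max']:g}), mean {epi['mean']:g}, "
            f"total {epi['total']:g}")
    if "responders" in report:
        lines.append(f"- Responders (>= 1 confirmed neoantigen): {report['responders']}")
    if "immunogenic_epitopes" in report:
        lines.append(f"- Immunogenic epitopes: {report['immunogenic_epitopes']} "
                     f"({100 * report['immunogenic_fraction']:.0f}% of vaccinated)")
    if "ics_positive_strict" in report:
        lines.append(f"- ICS positive: {report['ics_positive_strict']} strict / "
                     f"{report['ics_positive_relaxed']} relaxed")
    if "recurrences" in report:
        lines.append(f"- Recurrences in vaccinated arm: {report['recurrences']}")
    rfs = report.get("rfs")
    if rfs:
        lines.append(f"- RFS at {rfs['horizon_months']:g} months (vaccinated): "
                     f"{100 * rfs['vaccinated']:.1f}%")
        if "control" in rfs:
            lines.append(f"- RFS at {rfs['horizon_months']:g} months (control): "
                         f"{100 * rfs['control']:.1f}%; log-rank p = "
                         f"{rfs['logrank_p']:.3g}")
    return "\n".join(lines) + "\n"


def report_to_json(report: Mapping[str, Any]) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=float)
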