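"""Tiered ELISpot response calling, ICS positivity, and per-patient summaries.

The monitoring workflow is tiered: a screening call on background-subtracted
IFN-gamma ELISpot means (post-vaccination mean >= 50 SFC/1e6 and >= 2x the
pre-vaccination mean), then a confirmatory one-sided Welch t-test comparing
post- vs pre-vaccination replicate wells at alpha = 0.05.  A patient with at
least one confirmed neoantigen is a responder.  ICS positivity follows the
strict rule (post >= 2x pre AND post >= 1% IFN-gamma+ cells); a relaxed,
fold-only variant is reported alongside.  Epitope deconvolution labels each
confirmed response as focused (one overlapping peptide dominates) or mixed,
and records mutant-vs-wild-type minimal-peptide specificity.

Well counts arrive as a tidy table with columns patient, neoantigen,
stimulus (pooled-OP / OP1 / OP2 / OP3 / MT-S / WT-S / no-peptide), timepoint
(pre / post), well, count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CallerThresholds

STIMULI = ("pooled-OP", "OP1", "OP2", "OP3", "MT-S", "WT-S", "no-peptide")
PRE, POST = "pre", "post"


def subtract_background(condition_wells: Sequence[float],
                        no_peptide_wells: Sequence[float]) -> float:
    """Background-subtracted mean SFC: mean(condition) - mean(no-peptide),
    floored at zero."""
    if len(condition_wells) == 0 or len(no_peptide_wells) == 0:
        raise ValueError("need at least one well per condition")
    return max(0.0, float(np.mean(condition_wells)) - float(np.mean(no_peptide_wells)))


def welch_t_one_sided(pre: Sequence[float], post: Sequence[float],
                      welch: bool = True) -> tuple[float, float]:
    """One-sided two-sample t-test of post > pre, computed from first
    principles (Welch by default, pooled-variance otherwise).

    Degenerate zero-variance arms resolve by sign of the mean difference.
    Returns (t, p)."""
    x, y = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need >= 2 replicate wells per arm")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            return (math.inf if my > mx else (-math.inf if my < mx else 0.0),
                    0.0 if my > mx else 1.0)
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1 / nx + 1 / ny)
        if se2 == 0:
            return (math.inf if my > mx else (-math.inf if my < mx else 0.0),
                    0.0 if my > mx else 1.0)
        df = nx + ny - 2
    t = (my - mx) / math.sqrt(se2)
    return t, float(stats.t.sf(t, df))


def screening_call(pre_wells: Sequence[float], post_wells: Sequence[float],
                   background_pre: Sequence[float], background_post: Sequence[float],
                   thresholds: CallerThresholds | None = None) -> bool:
    """Screening positivity on background-subtracted means."""
    thr = thresholds or CallerThresholds()
    adj_pre = subtract_background(pre_wells, background_pre)
    adj_post = subtract_background(post_wells, background_post)
    return adj_post >= thr.min_sfc and adj_post >= thr.min_fold * max(adj_pre, 1.0)


def confirmatory_call(pre_wells: Sequence[float], post_wells: Sequence[float],
                      background_pre: Sequence[float], background_post: Sequence[float],
                      thresholds: CallerThresholds | None = None,
                      ) -> tuple[float, bool, bool]:
    """Confirmatory t-test on background-subtracted well counts.

    Subtracts the background mean from each replicate (unfloored, so the test
    statistic is a pure shift of the raw wells) and tests post > pre.
    Returns (p, confirmed, indeterminate); with fewer than 2 wells per arm
    the call is indeterminate rather than confirmed."""
    thr = thresholds or CallerThresholds()
    if len(pre_wells) < 2 or len(post_wells) < 2:
        return math.nan, False, True
    adj_pre = np.asarray(pre_wells, float) - float(np.mean(background_pre))
    adj_post = np.asarray(post_wells, float) - float(np.mean(background_post))
    _, p = welch_t_one_sided(adj_pre, adj_post, welch=thr.welch)
    return p, p < thr.alpha, False


def _wells(group: pd.DataFrame, stimulus: str, timepoint: str) -> np.ndarray:
    sel = group[(group["stimulus"] == stimulus) & (group["timepoint"] == timepoint)]
    return sel["count"].to_numpy(dtype=float)


def call_responses(elispot: pd.DataFrame,
                   thresholds: CallerThresholds | None = None) -> pd.DataFrame:
    """Screening + confirmatory calls for every patient x neoantigen.

    Output columns: patient, neoantigen, mean_sfc_pre, mean_sfc_post,
    screening_positive, confirmatory_p, confirmed, q_value (Benjamini-Hochberg
    across all tested neoantigens, reported alongside but not used for the
    calls, which follow the per-neoantigen convention)."""
    thr = thresholds or CallerThresholds()
    rows = []
    for patient, pgroup in elispot.groupby("patient", sort=True):
        bg = {tp: _wells(pgroup, "no-peptide", tp) for tp in (PRE, POST)}
        for neo, group in pgroup[pgroup["stimulus"] != "no-peptide"].groupby(
                "neoantigen", sort=True):
            pre = _wells(group, "pooled-OP", PRE)
            post = _wells(group, "pooled-OP", POST)
            if len(pre) == 0 or len(post) == 0:
                continue
            adj_pre = subtract_background(pre, bg[PRE])
            adj_post = subtract_background(post, bg[POST])
            screening = screening_call(pre, post, bg[PRE], bg[POST], thr)
            p, confirmed, indet = (math.nan, False, False)
            if screening:
                p, confirmed, indet = confirmatory_call(pre, post, bg[PRE], bg[POST], thr)
            rows.append({"patient": patient, "neoantigen": neo,
                         "mean_sfc_pre": adj_pre, "mean_sfc_post": adj_post,
                         "screening_positive": screening, "confirmatory_p": p,
                         "confirmed": confirmed, "indeterminate": indet})
    calls = pd.DataFrame(rows, columns=["patient", "neoantigen", "mean_sfc_pre",
                                        "mean_sfc_post", "screening_positive",
                                        "confirmatory_p", "confirmed", "indeterminate"])
    calls["q_value"] = math.nan
    tested = calls["confirmatory_p"].notna()
    if tested.any():
        calls.loc[tested, "q_value"] = multipletests(
            calls.loc[tested, "confirmatory_p"], method="fdr_bh")[1]
    return calls


def classify_responder(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-patient summary: responder iff >= 1 confirmed neoantigen, with
    immunogenic / non-immunogenic counts."""
    out = calls.groupby("patient", sort=True).agg(
        n_neoantigens=("neoantigen", "size"),
        n_confirmed=("confirmed", "sum"),
    ).reset_index()
    out["n_nonimmunogenic"] = out["n_neoantigens"] - out["n_confirmed"]
    out["responder"] = out["n_confirmed"] >= 1
    return out


def cumulative_sfc(calls: pd.DataFrame, timepoint: str) -> pd.Series:
    """Per-patient sum of background-subtracted means over all vaccinated
    neoantigens at a timepoint (the cumulative SFC/1e6 readout)."""
    col = {PRE: "mean_sfc_pre", POST: "mean_sfc_post"}[timepoint]
    return calls.groupby("patient", sort=True)[col].sum()


@dataclass(frozen=True)
class DeconvolutionResult:
    patient: str
    neoantigen: str
    pattern: str          # focused | mixed
    dominant_op: str | None
    op_signals: tuple[float, ...]
    mt_specific: bool
    mt_s_sfc: float
    wt_s_sfc: float


def deconvolve(elispot: pd.DataFrame, patient: str, neoantigen: str,
               thresholds: CallerThresholds | None = None) -> DeconvolutionResult:
    """Attribute a confirmed response to individual overlapping peptides.

    focused: one OP carries >= dominance_fraction of the summed adjusted OP
    signal (the pattern seen when the minimal class I epitope lies wholly
    within one OP); otherwise mixed.  mt_specific: adjusted MT-S signal is at
    least min_fold x the (floored) adjusted WT-S signal."""
    thr = thresholds or CallerThresholds()
    pgroup = elispot[elispot["patient"] == patient]
    bg_post = _wells(pgroup, "no-peptide", POST)
    group = pgroup[pgroup["neoantigen"] == neoantigen]
    ops = ["OP1", "OP2", "OP3"]
    signals = []
    for op in ops:
        wells = _wells(group, op, POST)
        signals.append(subtract_background(wells, bg_post) if len(wells) else 0.0)
    total = sum(signals)
    if total > 0 and max(signals) / total >= thr.dominance_fraction:
        pattern, dominant = "focused", ops[int(np.argmax(signals))]
    else:
        pattern, dominant = "mixed", None
    mt_wells, wt_wells = _wells(group, "MT-S", POST), _wells(group, "WT-S", POST)
    mt_s = subtract_background(mt_wells, bg_post) if len(mt_wells) else 0.0
    wt_s = subtract_background(wt_wells, bg_post) if len(wt_wells) else 0.0
    return DeconvolutionResult(patient, neoantigen, pattern, dominant,
                               tuple(signals), mt_s >= thr.min_fold * max(wt_s, 1.0),
                               mt_s, wt_s)


def ics_call(percent_pre: float, percent_post: float,
             thresholds: CallerThresholds | None = None) -> tuple[bool, bool]:
    """ICS positivity: (strict, relaxed).

    strict: post >= ics_min_fold x pre AND post >= ics_min_percent (the
    rigorous rule); relaxed drops the minimum-percent floor, so the strict
    positive set is always a subset of the relaxed one."""
    thr = thresholds or CallerThresholds()
    if not (0 <= percent_pre <= 100 and 0 <= percent_post <= 100):
        raise ValueError("ICS percentages must be in [0, 100]")
    relaxed = percent_post >= thr.ics_min_fold * percent_pre and percent_post > 0
    strict = relaxed and percent_post >= thr.ics_min_percent
    return strict, relaxed


def ics_calls(ics: pd.DataFrame,
              thresholds: CallerThresholds | None = None) -> pd.DataFrame:
    """Vectorized ICS calls over a tidy table with columns patient,
    neoantigen, subset, percent_pre, percent_post."""
    out = ics.copy()
    pairs = [ics_call(a, b, thresholds)
             for a, b in zip(out["percent_pre"], out["percent_post"])]
    out["ics_positive_strict"] = [s for s, _ in pairs]
    out["ics_positive_relaxed"] = [r for _, r in pairs]
    return out
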