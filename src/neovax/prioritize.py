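"""Epitope candidate scoring, filtering, ranking and vaccine selection.

A candidate is a minimal mutant peptide / HLA allele pair annotated with the
ensemble of predicted binding affinities and with the variant's expression,
clonality and driver status.  The filter rule is:

    passes = median mutant IC50 < 500 nM
             AND expressed (TPM > 0 and >= 1 mutant-supporting RNA read)
             AND (mutation not on an HLA anchor position OR WT/MT fold change > 1)
             AND no exact match in the wild-type proteome

Candidates are ranked by a deterministic lexicographic key (passing first,
then known driver genes, clonal before subclonal variants, ascending median
mutant IC50, descending fold change, id as tie-break), one best candidate per
window; the top windows, between 4 and 20 per patient, form the vaccine.  If
fewer than 4 windows pass, thresholds are relaxed stepwise (IC50 cutoff x2,
then the mutant-allele expression requirement is dropped) and ranking is
redone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PrioritizationThresholds
from .windows import FRAMESHIFT, MISSENSE, MinimalEpitopePair

CLONAL = "clonal"
SUBCLONAL = "subclonal"

#: candidate-table columns required by apply_filters / rank_and_select
CANDIDATE_COLUMNS = [
    "patient_id", "window_id", "allele", "mt_peptide", "wt_peptide", "length",
    "mutation_pos_in_peptide", "variant_type", "median_mt_ic50", "median_wt_ic50",
    "fold_change", "anchor_overlap", "clonality", "tpm", "rna_alt_reads",
    "proteome_match", "driver_flag",
]


@dataclass(frozen=True)
class BindingEnsemble:
    """Per-algorithm IC50s with their medians and the WT/MT fold change.

    ``fold_change`` is median WT IC50 / median MT IC50, so values > 1 mean the
    mutant binds tighter than the wild type.  Both WT fields are None for
    frameshift peptides, which have no wild-type counterpart.
    """

    mt_scores: tuple[float, ...]
    wt_scores: tuple[float, ...] | None
    median_mt_ic50: float
    median_wt_ic50: float | None
    fold_change: float | None


def aggregate_ensemble(mt_scores: Sequence[float],
                       wt_scores: Sequence[float] | None = None) -> BindingEnsemble:
    """Median-aggregate per-algorithm IC50s (even counts average the middle two)."""
    if len(mt_scores) == 0:
        raise ValueError("need at least one mutant IC50")
    if wt_scores is not None and len(wt_scores) != len(mt_scores):
        raise ValueError("WT score list must match MT list length")
    med_mt = float(np.median(mt_scores))
    if wt_scores is None:
        return BindingEnsemble(tuple(mt_scores), None, med_mt, None, None)
    med_wt = float(np.median(wt_scores))
    return BindingEnsemble(tuple(mt_scores), tuple(wt_scores), med_mt, med_wt,
                           med_wt / med_mt)


def anchor_overlap(pair: MinimalEpitopePair,
                   anchor_positions: Iterable[int] | None = None) -> bool:
    """True iff the mutated residue sits on an HLA anchor position.

    Anchors default to position 2 and the C-terminus (given as -1 or as the
    literal peptide length).  Frameshift peptides are never anchor-overlapping
    by convention.
    """
    if pair.mutation_pos_in_peptide is None:
        return False
    length = len(pair.mt_peptide)
    anchors = {2, length} if anchor_positions is None else {
        length if a == -1 else a for a in anchor_positions}
    return pair.mutation_pos_in_peptide in anchors


class ProteomeIndex:
    """Exact-substring screen against the wild-type proteome."""

    def __init__(self, proteome: Mapping[str, str]):
        self._joined = "#".join(proteome.values())

    def contains(self, peptide: str) -> bool:
        return peptide in self._joined


def screen_proteome(mt_peptide: str,
                    reference_proteome: Mapping[str, str] | ProteomeIndex) -> bool:
    """True iff the mutant peptide occurs verbatim in any reference protein."""
    if isinstance(reference_proteome, ProteomeIndex):
        return reference_proteome.contains(mt_peptide)
    return any(mt_peptide in seq for seq in reference_proteome.values())


def classify_clonality(vaf: float, patient_max_vaf: float,
                       ratio_threshold: float = 0.5) -> str:
    """Clonal iff VAF >= ratio_threshold x the patient's maximum VAF."""
    if patient_max_vaf <= 0:
        raise ValueError("patient_max_vaf must be positive")
    return CLONAL if vaf >= ratio_threshold * patient_max_vaf else SUBCLONAL


def apply_filters(candidates: pd.DataFrame,
                  thresholds: PrioritizationThresholds | None = None) -> pd.DataFrame:
    """Evaluate the filter rule on a candidate table.

    Returns a copy with boolean ``passes`` and a ``reasons`` column listing
    every failed clause (comma-separated codes: ic50, expression, anchor_fold,
    proteome_match, coverage)."""
    thr = thresholds or PrioritizationThresholds()
    df = candidates.copy()
    fold = df["fold_change"].astype(float)
    clauses = {
        "ic50": df["median_mt_ic50"] < thr.ic50_max,
        "expression": (df["tpm"] > 0) & (df["rna_alt_reads"] >= thr.min_rna_alt_reads),
        "anchor_fold": ~df["anchor_overlap"] | (fold > thr.min_anchor_fold),
        "proteome_match": ~df["proteome_match"].astype(bool),
    }
    if thr.min_coverage is not None and "coverage" in df.columns:
        clauses["coverage"] = df["coverage"] >= thr.min_coverage
    passes = np.ones(len(df), dtype=bool)
    reasons = [[] for _ in range(len(df))]
    for code, ok in clauses.items():
        ok = np.asarray(ok.fillna(False) if hasattr(ok, "fillna") else ok, dtype=bool)
        passes &= ok
        for i in np.flatnonzero(~ok):
            reasons[i].append(code)
    df["passes"] = passes
    df["reasons"] = [",".join(r) for r in reasons]
    return df


def _rank_sorted(df: pd.DataFrame) -> pd.DataFrame:
    """Sort candidates by the deterministic lexicographic rank key."""
    key = df.assign(
        _fail=~df["passes"],
        _nondriver=~df["driver_flag"].astype(bool),
        _subclonal=df["clonality"].ne(CLONAL),
        _neg_fold=-df["fold_change"].astype(float).fillna(-np.inf),
    )
    return key.sort_values(
        ["_fail", "_nondriver", "_subclonal", "median_mt_ic50", "_neg_fold",
         "window_id", "mt_peptide", "allele"],
        kind="mergesort").drop(columns=["_fail", "_nondriver", "_subclonal", "_neg_fold"])


@dataclass
class VaccineSelection:
    """Ordered vaccine content for one patient.

    ``windows`` are the selected window ids in rank order; ``representatives``
    holds the best candidate row per selected window; ``relaxation_step`` is 0
    if the default thresholds sufficed.  ``status`` is ok / relaxed / empty.
    """

    patient_id: str
    windows: list[str]
    representatives: pd.DataFrame
    relaxation_step: int
    status: str

    @property
    def n_selected(self) -> int:
        return len(self.windows)


def rank_and_select(candidates: pd.DataFrame,
                    thresholds: PrioritizationThresholds | None = None,
                    patient_id: str | None = None) -> VaccineSelection:
    """Rank a patient's candidates and select 4-20 windows for the vaccine.

    One best candidate represents each window; only windows whose
    representative passes the filters are selectable.  If fewer than
    ``min_select`` windows pass, the relaxation schedule is applied and the
    ranking redone; the output records the relaxation step used.  The result
    is deterministic and invariant to the input row order.
    """
    thr = thresholds or PrioritizationThresholds()
    if patient_id is None:
        patient_id = str(candidates["patient_id"].iloc[0]) if len(candidates) else "?"
    if len(candidates) == 0:
        return VaccineSelection(patient_id, [], candidates.copy(), 0, "empty")

    step = 0
    for step in range(3):
        filtered = apply_filters(candidates, thr.relaxed(step))
        ranked = _rank_sorted(filtered)
        reps = ranked.drop_duplicates(subset="window_id", keep="first")
        n_passing = int(reps["passes"].sum())
        if n_passing >= thr.min_select:
            break
    selected = reps[reps["passes"]].head(thr.max_select)
    if len(selected) == 0:
        status = "empty"
    elif step > 0:
        status = "relaxed"
    else:
        status = "ok"
    return VaccineSelection(patient_id, selected["window_id"].tolist(),
                            selected.reset_index(drop=True), step, status)
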