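"""End-to-end orchestration: cohort simulation -> vaccine design ->
construct assembly -> assay simulation -> response calling -> outcomes.

``simulate_cohort`` runs the generative half (everything with known ground
truth); ``analyze_cohort`` runs the analysis half on its outputs exactly as
it would run on real monitoring data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import cohort as syn
from .binding import ToyBindingPredictor
from .config import CallerThresholds, CohortConfig, ExpansionConfig, PrioritizationThresholds
from .construct import (OverlappingPeptidePanel, VaccineConstruct,
                        assemble_polyepitope, design_overlapping_peptides,
                        load_ubiquitin, mutate_ubiquitin)
from .elispot import call_responses, classify_responder, ics_calls
from .prioritize import (CANDIDATE_COLUMNS, ProteomeIndex, VaccineSelection,
                         classify_clonality, rank_and_select)
from .report import cohort_report
from .tcr import summarize_repertoires
from .windows import (MISSENSE, PeptideWindow, SomaticVariant, apply_variant,
                      enumerate_minimal_epitopes, extract_window)


def variants_from_table(variants: pd.DataFrame) -> list[SomaticVariant]:
    """Materialize SomaticVariant objects from a tidy variant table."""
    out = []
    for row in variants.itertuples(index=False):
        out.append(SomaticVariant(
            patient_id=row.patient_id, protein_id=row.protein_id,
            position=int(row.position), ref=row.ref, alt=row.alt,
            variant_type="missense" if row.type == "missense" else "frameshift",
            vaf=float(row.vaf), tpm=float(row.tpm),
            rna_alt_reads=int(row.rna_alt_reads), driver_flag=bool(row.driver_flag)))
    return out


def build_windows(variants: list[SomaticVariant],
                  proteome: dict[str, str]) -> dict[str, PeptideWindow]:
    """Mutant/wild-type windows for every variant, keyed by neoantigen id."""
    windows: dict[str, PeptideWindow] = {}
    for v in variants:
        mt_protein = apply_variant(proteome[v.protein_id], v)
        windows[v.neoantigen_id] = extract_window(proteome[v.protein_id], mt_protein, v)
    return windows


def build_candidates(windows: dict[str, PeptideWindow],
                     variants: list[SomaticVariant],
                     hla: dict[str, list[str]],
                     proteome: dict[str, str],
                     predictor: ToyBindingPredictor,
                     clonality_ratio: float = 0.5) -> pd.DataFrame:
    """Enumerate and annotate every minimal epitope / allele candidate.

    Binding IC50s are median-aggregated over the predictor's algorithms;
    candidates carry anchor overlap, clonality (relative to the patient's
    maximum VAF), expression, proteome-screen and driver annotations."""
    var_by_id = {v.neoantigen_id: v for v in variants}
    max_vaf = {}
    for v in variants:
        max_vaf[v.patient_id] = max(max_vaf.get(v.patient_id, 0.0), v.vaf)
    index = ProteomeIndex(proteome)

    rows = []
    for wid, window in windows.items():
        v = var_by_id[wid]
        for pair in enumerate_minimal_epitopes(window, hla[v.patient_id]):
            rows.append((v.patient_id, wid, pair.allele, pair.mt_peptide,
                         pair.wt_peptide, len(pair.mt_peptide),
                         pair.mutation_pos_in_peptide, window.variant_type, v))
    if not rows:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)

    # median IC50 across algorithms for every unique (peptide, allele)
    unique: dict[tuple[str, str], float] = {}
    by_group: dict[tuple[int, str], set[str]] = {}
    for _, _, allele, mt, wt, length, _, _, _ in rows:
        by_group.setdefault((length, allele), set()).add(mt)
        if wt is not None:
            by_group.setdefault((length, allele), set()).add(wt)
    for (length, allele), peps in by_group.items():
        peps = sorted(peps)
        scores = np.stack([predictor.predict_batch(peps, allele, a)
                           for a in predictor.algorithms])
        med = np.median(scores, axis=0)
        for p, m in zip(peps, med):
            unique[(p, allele)] = float(m)

    records = []
    for patient, wid, allele, mt, wt, length, mut_pos, vtype, v in rows:
        med_mt = unique[(mt, allele)]
        med_wt = unique[(wt, allele)] if wt is not None else np.nan
        fold = med_wt / med_mt if wt is not None else np.nan
        anchor = mut_pos in (2, length) if mut_pos is not None else False
        records.append({
            "patient_id": patient, "window_id": wid, "allele": allele,
            "mt_peptide": mt, "wt_peptide": wt, "length": length,
            "mutation_pos_in_peptide": mut_pos, "variant_type": vtype,
            "median_mt_ic50": med_mt, "median_wt_ic50": med_wt,
            "fold_change": fold, "anchor_overlap": anchor,
            "clonality": classify_clonality(v.vaf, max_vaf[patient], clonality_ratio),
            "tpm": v.tpm, "rna_alt_reads": v.rna_alt_reads,
            "proteome_match": index.contains(mt), "driver_flag": v.driver_flag,
        })
    return pd.DataFrame.from_records(records, columns=CANDIDATE_COLUMNS)


@dataclass
class SyntheticCohort:
    """Everything one simulated trial produces, with ground truth."""

    config: CohortConfig
    proteome: dict[str, str]
    expression: pd.DataFrame
    hla: dict[str, list[str]]
    variants: pd.DataFrame
    windows: dict[str, PeptideWindow]
    candidates: pd.DataFrame
    selections: dict[str, VaccineSelection]
    constructs: dict[str, VaccineConstruct]
    panels: dict[str, OverlappingPeptidePanel]
    ground_truth: syn.GroundTruth
    elispot: pd.DataFrame
    ics: pd.DataFrame
    clonotypes: pd.DataFrame
    followup: pd.DataFrame

    @property
    def designs(self) -> dict[str, list[str]]:
        return {p: s.windows for p, s in self.selections.items()}


def simulate_cohort(config: CohortConfig | None = None,
                    prioritization: PrioritizationThresholds | None = None,
                    with_junction_report: bool = True) -> SyntheticCohort:
    """Generate a full synthetic trial: proteome, variants, vaccine designs,
    constructs, assays and follow-up, with ground-truth labels."""
    cfg = config or CohortConfig()
    thr = prioritization or PrioritizationThresholds()
    rng = np.random.default_rng(cfg.seed)
    predictor = ToyBindingPredictor(cfg.n_algorithms)

    proteome, expression = syn.generate_proteome(cfg, rng)
    hla = syn.assign_hla(cfg, rng)
    variant_table, proteome = syn.simulate_variants(proteome, expression, hla, cfg,
                                                    rng, predictor)
    variants = variants_from_table(variant_table)
    windows = build_windows(variants, proteome)
    candidates = build_candidates(windows, variants, hla, proteome, predictor,
                                  thr.clonality_ratio)

    selections, constructs, panels = {}, {}, {}
    ub_mut = mutate_ubiquitin(load_ubiquitin())
    for patient in syn.patient_ids(cfg):
        cand = candidates[candidates["patient_id"] == patient]
        sel = rank_and_select(cand, thr, patient_id=patient)
        selections[patient] = sel
        if sel.n_selected:
            seqs = [(wid, windows[wid].mt_sequence) for wid in sel.windows]
            constructs[patient] = assemble_polyepitope(
                ub_mut, seqs,
                predictor=predictor if with_junction_report else None,
                alleles=hla[patient] if with_junction_report else None)
            constructs[patient].patient_id = patient
            for wid, seq in seqs:
                panels[wid] = design_overlapping_peptides(seq, wid)

    designs = {p: s.windows for p, s in selections.items()}
    truth = syn.choose_ground_truth(designs, cfg, rng)
    elispot, ics, clonotypes = syn.simulate_assays(designs, truth, cfg, rng)
    followup = syn.simulate_followup(cfg, rng)
    return SyntheticCohort(cfg, proteome, expression, hla, variant_table, windows,
                           candidates, selections, constructs, panels, truth,
                           elispot, ics, clonotypes, followup)


@dataclass
class CohortAnalysis:
    calls: pd.DataFrame
    responders: pd.DataFrame
    ics_calls: pd.DataFrame
    expansion: pd.DataFrame
    repertoire_summaries: list
    report: dict[str, Any]


def analyze_cohort(cohort: SyntheticCohort,
                   caller: CallerThresholds | None = None,
                   expansion: ExpansionConfig | None = None,
                   horizon_months: float = 36.0) -> CohortAnalysis:
    """Run the monitoring analysis (ELISpot tiered calls, ICS rule, TCR
    expansion, survival) and assemble the cohort report."""
    calls = call_responses(cohort.elispot, caller)
    responders = classify_responder(calls)
    ics = ics_calls(cohort.ics, caller)
    expansion_table, summaries = summarize_repertoires(cohort.clonotypes, expansion)
    rep = cohort_report(cohort.selections, responders, ics, cohort.followup,
                        horizon_months)
    return CohortAnalysis(calls, responders, ics, expansion_table, summaries, rep)
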