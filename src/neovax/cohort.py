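"""Synthetic trial-cohort generators with known ground truth.

Everything downstream of sequencing — reference proteome, per-patient somatic
variants, HLA alleles, assay readouts, follow-up — is generated here so the
whole pipeline is testable without any protected patient data.  Defaults
emulate the study conditions: 18 patients, ~21.5 protein-altering expressed
mutations per patient (median), 97% missense / 3% frameshift, a minority
(~23%) of vaccinated epitopes truly immunogenic, no-peptide ELISpot
background of 10-120 SFC/1e6, and 2/18 recurrences against a historical
control arm with ~50% 3-year recurrence-free survival.

Strong binders are *planted*: for a configurable fraction of variants the
generator embeds an allele's consensus 9-mer, with position 5 replaced, into
the reference protein; the somatic variant restores the consensus residue.
The mutant 9-mer then scores far below 500 nM for that allele while the
wild-type peptide remains in the reference proteome, giving the cohort a
known set of recoverable vaccine epitopes.  All generators are deterministic
given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import AMINO_ACIDS, ToyBindingPredictor, allele_pool
from .config import CohortConfig

VARIANT_COLUMNS = ["patient_id", "protein_id", "position", "ref", "alt", "type",
                   "vaf", "tpm", "rna_alt_reads", "driver_flag", "planted_allele"]

_AA = np.array(list(AMINO_ACIDS))


class ConsistencyError(ValueError):
    """Ground truth refers to an epitope absent from the vaccine designs."""


@dataclass
class GroundTruth:
    """Truth labels for parameter-recovery tests.

    ``immunogenic_epitopes``: (patient, neoantigen id) pairs that truly drive
    post-vaccination signal; always a subset of the vaccinated epitopes.
    ``expanded_clonotypes``: (patient, condition, CDR3b) triples spiked with
    the configured expansion factor post-vaccination."""

    immunogenic_epitopes: set[tuple[str, str]] = field(default_factory=set)
    expanded_clonotypes: set[tuple[str, str, str]] = field(default_factory=set)


def patient_ids(cfg: CohortConfig) -> list[str]:
    return [f"SYN{i + 1:02d}" for i in range(cfg.n_patients)]


def generate_proteome(cfg: CohortConfig,
                      rng: np.random.Generator) -> tuple[dict[str, str], pd.DataFrame]:
    """Random reference proteome plus a per-transcript TPM table."""
    lo, hi = cfg.protein_length_range
    proteome: dict[str, str] = {}
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        proteome[f"PROT{i + 1:04d}"] = "".join(rng.choice(_AA, size=length))
    tpm = np.round(rng.lognormal(mean=np.log(10.0), sigma=1.0, size=cfg.n_proteins), 3)
    expression = pd.DataFrame({"protein_id": list(proteome), "tpm": tpm})
    return proteome, expression


def assign_hla(cfg: CohortConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Six class I alleles per patient, sampled from a 12-allele pool."""
    pool = allele_pool(12)
    return {p: sorted(rng.choice(pool, size=cfg.n_alleles_per_patient, replace=False))
            for p in patient_ids(cfg)}


def _plant_motif(proteome: dict[str, str], used: dict[str, list[tuple[int, int]]],
                 motif: str, rng: np.random.Generator,
                 margin: int = 12) -> tuple[str, int, str] | None:
    """Embed ``motif`` with position 5 replaced into a free proteome slot.

    Returns (protein_id, 1-based variant position, wild-type residue at that
    position).  The edited reference then differs from the motif at exactly
    the future mutation site."""
    wt_res = rng.choice([aa for aa in AMINO_ACIDS if aa not in (motif[4], "A")])
    planted = motif[:4] + wt_res + motif[5:]
    ids = list(proteome)
    for _ in range(200):
        pid = ids[int(rng.integers(len(ids)))]
        seq = proteome[pid]
        if len(seq) < 2 * margin + 9:
            continue
        start = int(rng.integers(margin, len(seq) - 9 - margin))
        span = (start - margin, start + 9 + margin)
        if any(a < span[1] and span[0] < b for a, b in used.get(pid, [])):
            continue
        proteome[pid] = seq[:start] + planted + seq[start + 9:]
        used.setdefault(pid, []).append(span)
        return pid, start + 5, wt_res
    return None


def simulate_variants(proteome: dict[str, str], expression: pd.DataFrame,
                      hla: Mapping[str, Sequence[str]], cfg: CohortConfig,
                      rng: np.random.Generator,
                      predictor: ToyBindingPredictor | None = None,
                      ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-patient somatic variant tables (and the motif-edited proteome).

    Counts are Poisson around the configured median; types are Bernoulli
    missense/frameshift at the configured fraction.  Planted strong-binder
    variants are always missense and always expressed; other variants are
    expressed (RNA support > 0) with probability 0.9.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    predictor = predictor or ToyBindingPredictor(cfg.n_algorithms)
    proteome = dict(proteome)
    tpm_of = dict(zip(expression["protein_id"], expression["tpm"]))
    used: dict[str, list[tuple[int, int]]] = {}
    rows = []
    for patient in patient_ids(cfg):
        n = max(1, int(rng.poisson(cfg.mutations_per_patient_median)))
        taken: set[tuple[str, int]] = set()
        for _ in range(n):
            is_missense = rng.random() < cfg.missense_fraction
            planted = is_missense and rng.random() < cfg.binder_fraction
            allele = ""
            if planted:
                allele = str(rng.choice(hla[patient]))
                slot = _plant_motif(proteome, used, predictor.consensus_motif(allele), rng)
                if slot is None:  # proteome saturated; fall back to a passenger
                    planted, allele = False, ""
                else:
                    pid, pos, ref = slot
                    alt = predictor.consensus_motif(allele)[4]
            if not planted:
                ids = list(proteome)
                for _ in range(100):
                    pid = ids[int(rng.integers(len(ids)))]
                    pos = int(rng.integers(1, len(proteome[pid]) + 1))
                    if (pid, pos) not in taken:
                        break
                ref = proteome[pid][pos - 1]
                if is_missense:
                    alt = str(rng.choice([aa for aa in AMINO_ACIDS if aa != ref]))
                else:
                    tail_len = int(rng.integers(8, 30))
                    alt = "".join(rng.choice(_AA, size=tail_len)) + "*"
            taken.add((pid, pos))
            if not planted:
                # reserve the site so a later motif plant cannot rewrite it
                used.setdefault(pid, []).append((pos - 1, pos))
            expressed = planted or rng.random() < 0.9
            rows.append({
                "patient_id": patient, "protein_id": pid, "position": pos,
                "ref": ref, "alt": alt,
                "type": "missense" if is_missense else "frameshift",
                "vaf": round(float(rng.uniform(0.05, 0.6)), 4),
                "tpm": tpm_of[pid] if expressed else 0.0,
                "rna_alt_reads": int(rng.poisson(8) + 1) if expressed else 0,
                "driver_flag": bool(rng.random() < 0.15),
                "planted_allele": allele,
            })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS), proteome


def choose_ground_truth(designs: Mapping[str, Sequence[str]], cfg: CohortConfig,
                        rng: np.random.Generator) -> GroundTruth:
    """Label each vaccinated epitope truly immunogenic with probability
    ``immunogenic_fraction``."""
    truth = GroundTruth()
    for patient in sorted(designs):
        for neo in designs[patient]:
            if rng.random() < cfg.immunogenic_fraction:
                truth.immunogenic_epitopes.add((patient, neo))
    return truth


def _nb(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    """Negative-binomial counts with the given mean and dispersion (size)."""
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_assays(designs: Mapping[str, Sequence[str]], truth: GroundTruth,
                    cfg: CohortConfig, rng: np.random.Generator,
                    n_wells: int = 3,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ELISpot wells, ICS percentages and clonotype tables for every design.

    Truly immunogenic epitopes get a post-vaccination ELISpot effect of
    250-5000 SFC/1e6 over background (log-uniform), an ICS signal satisfying
    the strict positivity rule with high probability, and 1-2 clonotypes
    expanded by ``expansion_factor`` in the post repertoire.  Everything else
    shares the background distribution pre and post.  No-peptide control
    means are uniform in 10-120 SFC/1e6.
    """
    for patient, neo in truth.immunogenic_epitopes:
        if neo not in set(designs.get(patient, ())):
            raise ConsistencyError(
                f"ground-truth epitope {neo!r} is not in patient {patient!r}'s vaccine")
    eli_rows, ics_rows, clono_rows = [], [], []
    for patient in sorted(designs):
        bg_mean = {tp: float(rng.uniform(10, 120)) for tp in ("pre", "post")}
        for tp in ("pre", "post"):
            for w, c in enumerate(_nb(rng, bg_mean[tp], cfg.elispot_noise, n_wells)):
                eli_rows.append((patient, "", "no-peptide", tp, w, int(c)))
        for neo in designs[patient]:
            immunogenic = (patient, neo) in truth.immunogenic_epitopes
            effect = float(10 ** rng.uniform(np.log10(250), np.log10(5000))) \
                if immunogenic else 0.0
            if rng.random() < 0.6:
                op_split = np.array([0.1, 0.1, 0.1])
                op_split[int(rng.integers(3))] = 0.8
            else:
                op_split = rng.dirichlet([8, 8, 8])
            for tp in ("pre", "post"):
                eff = effect if tp == "post" else 0.0
                means = {"pooled-OP": eff, "OP1": eff * op_split[0],
                         "OP2": eff * op_split[1], "OP3": eff * op_split[2],
                         "MT-S": eff, "WT-S": 0.02 * eff}
                for stim, m in means.items():
                    counts = _nb(rng, bg_mean[tp] + m, cfg.elispot_noise, n_wells)
                    for w, c in enumerate(counts):
                        eli_rows.append((patient, neo, stim, tp, w, int(c)))
            for subset in ("CD4", "CD8"):
                pre_pct = float(np.clip(rng.normal(0.2, 0.1), 0.0, 100.0))
                signal = immunogenic and (subset == "CD8" or rng.random() < 0.5)
                post_pct = float(np.clip(
                    rng.normal(2.5, cfg.ics_noise) if signal else rng.normal(0.2, 0.1),
                    0.0, 100.0))
                ics_rows.append((patient, neo, subset, round(pre_pct, 3),
                                 round(post_pct, 3)))
            if immunogenic:
                clono_rows.extend(_simulate_repertoire(patient, neo, True, truth,
                                                       cfg, rng))
        clono_rows.extend(_simulate_repertoire(patient, "control", False, truth,
                                               cfg, rng))
    elispot = pd.DataFrame(eli_rows, columns=["patient", "neoantigen", "stimulus",
                                              "timepoint", "well", "count"])
    ics = pd.DataFrame(ics_rows, columns=["patient", "neoantigen", "subset",
                                          "percent_pre", "percent_post"])
    clonotypes = pd.DataFrame(clono_rows, columns=["patient", "condition",
                                                   "timepoint", "cdr3b", "count"])
    return elispot, ics, clonotypes


def _random_cdr3(rng: np.random.Generator) -> str:
    return "CASS" + "".join(rng.choice(_AA, size=int(rng.integers(5, 10)))) + "F"


def _simulate_repertoire(patient: str, condition: str, expand: bool,
                         truth: GroundTruth, cfg: CohortConfig,
                         rng: np.random.Generator) -> list[tuple]:
    """One pre/post repertoire pair; truth clonotypes are spiked by the
    expansion factor in the post sample."""
    n = cfg.n_clonotypes
    seen: set[str] = set()
    cdr3 = []
    while len(cdr3) < n:
        name = _random_cdr3(rng)
        if name not in seen:
            seen.add(name)
            cdr3.append(name)
    base = 1.0 / np.arange(1, n + 1) ** 1.1
    base /= base.sum()
    rows = []
    pre_counts = rng.multinomial(cfg.clonotype_depth, base)
    post_freq = base.copy()
    if expand and cfg.expansion_factor != 1.0:
        k = 1 + int(rng.random() < 0.4)
        lo = min(50, max(1, n // 5))            # mid-frequency ranks
        hi = max(lo + k, min(500, n))
        spiked = rng.choice(np.arange(lo, hi), size=k, replace=False)
        post_freq[spiked] *= cfg.expansion_factor
        post_freq /= post_freq.sum()
        for i in spiked:
            truth.expanded_clonotypes.add((patient, condition, cdr3[int(i)]))
    post_counts = rng.multinomial(cfg.clonotype_depth, post_freq)
    for tp, counts in (("pre", pre_counts), ("post", post_counts)):
        for name, c in zip(cdr3, counts):
            if c > 0:
                rows.append((patient, condition, tp, name, int(c)))
    return rows


def simulate_followup(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Vaccinated-arm follow-up (Bernoulli recurrence at the configured rate)
    plus a higher-hazard historical control arm.

    Vaccinated time zero is the first injection; control times are already on
    the reset clock (4 months after surgery), so the arms are directly
    comparable.  All times are positive."""
    rows = []
    for patient in patient_ids(cfg):
        event = bool(rng.random() < cfg.recurrence_rate)
        time = float(rng.uniform(6, 30)) if event else float(rng.uniform(24, 48))
        rows.append((patient, "vaccinated", round(time, 2), event))
    for i in range(cfg.n_controls):
        t_event = float(rng.exponential(1.0 / cfg.control_hazard))
        t_cens = float(rng.uniform(24, 60))
        rows.append((f"CTRL{i + 1:03d}", "control",
                     round(max(min(t_event, t_cens), 0.01), 2), t_event <= t_cens))
    return pd.DataFrame(rows, columns=["subject", "arm", "time_months", "event"])
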