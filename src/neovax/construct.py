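"""Polyepitope DNA vaccine construct assembly and peptide-panel design.

The vaccine insert is a single open reading frame: mutant ubiquitin (G76V, a
non-cleavable fusion that routes the polyprotein into proteasomal processing)
fused N-terminally to the selected neoantigen windows concatenated in rank
order, with no linkers by default.  The protein is reverse-translated with the
most-frequent human codon per residue, so the emitted DNA translates exactly
back to the protein under the standard genetic code.

For immune monitoring, each ~25-mer window is tiled into 15-16-mer
overlapping peptides (OPs) with 11-residue overlaps; a 25-mer yields exactly
three OPs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .binding import ToyBindingPredictor
from .prioritize import aggregate_ensemble

UBIQUITIN_LENGTH = 76
OP_MIN, OP_MAX, OP_OVERLAP = 15, 16, 11


class ConstructError(ValueError):
    pass


def load_ubiquitin() -> str:
    """Canonical human ubiquitin monomer (76 aa) from packaged data."""
    text = resources.files("neovax.data").joinpath("ubiquitin_human.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


def mutate_ubiquitin(wild_type_ub: str) -> str:
    """G76V: validate a 76-residue ubiquitin ending in G and substitute V."""
    if len(wild_type_ub) != UBIQUITIN_LENGTH:
        raise ConstructError(f"ubiquitin must be {UBIQUITIN_LENGTH} aa, got {len(wild_type_ub)}")
    if wild_type_ub[-1] != "G":
        raise ConstructError(f"residue 76 must be G, got {wild_type_ub[-1]!r}")
    return wild_type_ub[:-1] + "V"


class CodonTable:
    """Codon usage table mapping each residue to its most frequent codon
    (ties broken by alphabetical codon)."""

    def __init__(self, rows: list[tuple[str, str, float]], table_id: str = "custom"):
        self.table_id = table_id
        self.codon_to_residue = {c: r for c, r, _ in rows}
        best: dict[str, tuple[float, str]] = {}
        for codon, residue, freq in rows:
            if freq <= 0:
                continue
            cur = best.get(residue)
            # higher frequency wins; on ties the alphabetically smaller codon
            if cur is None or (freq, _neg(codon)) > (cur[0], _neg(cur[1])):
                best[residue] = (freq, codon)
        self.best_codon = {r: c for r, (_, c) in best.items()}

    @classmethod
    def human(cls) -> "CodonTable":
        text = resources.files("neovax.data").joinpath("codon_usage_human.tsv").read_text()
        rows = []
        for rec in csv.DictReader(text.splitlines(), delimiter="\t"):
            rows.append((rec["codon"], rec["residue"], float(rec["freq_per_1000"])))
        return cls(rows, table_id="human_kazusa")


class _neg(str):
    """Reverses string comparison so max() prefers the alphabetically smaller codon."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def reverse_translate(protein: str, codon_table: CodonTable | None = None) -> str:
    """Deterministic reverse translation: most frequent codon per residue."""
    table = codon_table or CodonTable.human()
    try:
        return "".join(table.best_codon[aa] for aa in protein)
    except KeyError as exc:
        raise ConstructError(f"residue {exc.args[0]!r} absent from codon table") from None


@dataclass
class VaccineConstruct:
    """Assembled insert: Ub(G76V) + ordered windows, as protein and DNA."""

    patient_id: str
    ub_mut_sequence: str
    epitope_order: list[str]
    window_sequences: list[str]
    protein_sequence: str
    dna_sequence: str
    codon_table_id: str
    junction_report: pd.DataFrame = field(repr=False, default=None)


def junction_peptides(segments: list[str], lengths=(8, 9, 10, 11)) -> pd.DataFrame:
    """Every novel 8-11-mer spanning a junction between consecutive segments.

    A k-mer spans junction j (0-based, between segments j and j+1) when it
    contains at least one residue from each side."""
    protein = "".join(segments)
    bounds = np.cumsum([len(s) for s in segments])[:-1]
    rows = []
    for j, b in enumerate(bounds):
        for k in lengths:
            for s in range(max(0, b - k + 1), min(b, len(protein) - k + 1)):
                rows.append({"junction": j, "start": s, "length": k,
                             "peptide": protein[s: s + k]})
    return pd.DataFrame(rows, columns=["junction", "start", "length", "peptide"])


def assemble_polyepitope(ub_mut: str, selection_windows: list[tuple[str, str]],
                         codon_table: CodonTable | None = None,
                         linker: str = "",
                         append_stop: bool = True,
                         predictor: ToyBindingPredictor | None = None,
                         alleles: list[str] | None = None,
                         ic50_flag_threshold: float = 500.0) -> VaccineConstruct:
    """Fuse Ub(G76V) to the selected windows (rank order, no linker by
    default), reverse-translate, and report junction-spanning peptides.

    The junction report is informational only: peptides crossing a window
    junction are novel sequence not present in the patient's tumor, and any
    that a predictor scores under ``ic50_flag_threshold`` for a patient allele
    are flagged, but windows are never reordered automatically.
    """
    if not selection_windows:
        raise ConstructError("selection is empty")
    ids = [w for w, _ in selection_windows]
    if len(set(ids)) != len(ids):
        raise ConstructError("duplicate window ids in selection")
    segments = [ub_mut]
    for _, seq in selection_windows:
        if linker and len(segments) >= 1:
            segments.append(linker)
        segments.append(seq)
    protein = "".join(segments)
    table = codon_table or CodonTable.human()
    dna = reverse_translate(protein, table)
    if append_stop:
        dna += "TGA"

    report = junction_peptides(segments)
    if predictor is not None and alleles and len(report):
        flagged, best_allele, best_ic50 = [], [], []
        for pep in report["peptide"]:
            medians = {a: aggregate_ensemble(predictor.predict_ensemble(pep, a)).median_mt_ic50
                       for a in alleles}
            a_min = min(medians, key=medians.get)
            best_allele.append(a_min)
            best_ic50.append(medians[a_min])
            flagged.append(medians[a_min] < ic50_flag_threshold)
        report = report.assign(best_allele=best_allele, median_ic50=best_ic50,
                               flagged=flagged)
    return VaccineConstruct(
        patient_id="", ub_mut_sequence=ub_mut, epitope_order=ids,
        window_sequences=[s for _, s in selection_windows],
        protein_sequence=protein, dna_sequence=dna,
        codon_table_id=table.table_id, junction_report=report)


def construct_to_genbank(construct: VaccineConstruct, name: str = "insert") -> SeqRecord:
    """Minimal annotated GenBank record of the DNA insert (Ub(G76V) plus one
    feature per epitope window)."""
    rec = SeqRecord(Seq(construct.dna_sequence), id=name[:16], name=name[:16],
                    description=f"polyepitope insert {construct.patient_id}".strip(),
                    annotations={"molecule_type": "DNA"})
    pos = 0
    ub_len = len(construct.ub_mut_sequence) * 3
    rec.features.append(SeqFeature(FeatureLocation(pos, pos + ub_len), type="CDS",
                                   qualifiers={"label": ["ub_mut_G76V"]}))
    pos += ub_len
    for wid, seq in zip(construct.epitope_order, construct.window_sequences):
        rec.features.append(SeqFeature(FeatureLocation(pos, pos + len(seq) * 3),
                                       type="misc_feature",
                                       qualifiers={"label": [wid]}))
        pos += len(seq) * 3
    return rec


@dataclass(frozen=True)
class OverlappingPeptidePanel:
    """Monitoring peptides tiling one window: 15-16-mers overlapping by 11."""

    window_id: str
    peptides: tuple[str, ...]
    starts: tuple[int, ...]
    overlap: int
    short_window: bool

    def covers(self, window_length: int) -> bool:
        mask = np.zeros(window_length, dtype=bool)
        for s, p in zip(self.starts, self.peptides):
            mask[s: s + len(p)] = True
        return bool(mask.all())


def design_overlapping_peptides(window_sequence: str,
                                window_id: str = "") -> OverlappingPeptidePanel:
    """Tile a window with 15-16-mers overlapping by exactly 11 residues.

    The number of peptides is the smallest n with 4n + 11 <= W <= 5n + 11
    (W = window length); 16-mers are placed last so the final peptide ends
    exactly at the window end.  A 25-mer yields exactly three peptides.
    Windows shorter than 15 residues become a single flagged peptide.
    """
    w = len(window_sequence)
    if w < OP_MIN:
        return OverlappingPeptidePanel(window_id, (window_sequence,), (0,),
                                       OP_OVERLAP, True)
    n = -(-(w - OP_OVERLAP) // (OP_MAX - OP_OVERLAP))  # ceil((W-11)/5)
    n_long = w - OP_OVERLAP - (OP_MIN - OP_OVERLAP) * n  # count of 16-mers
    if n_long >= 0:
        lengths = [OP_MIN] * (n - n_long) + [OP_MAX] * n_long
        starts = list(np.cumsum([0] + [ln - OP_OVERLAP for ln in lengths[:-1]]))
    else:
        # lengths like 17/18/22 are not exactly tileable at overlap 11;
        # greedy 15-mers with the last one shifted to end at the window end
        # (its overlap then exceeds 11)
        lengths = [OP_MIN] * n
        starts = [i * (OP_MIN - OP_OVERLAP) for i in range(n - 1)] + [w - OP_MIN]
    peptides = [window_sequence[s: s + ln] for s, ln in zip(starts, lengths)]
    return OverlappingPeptidePanel(window_id, tuple(peptides),
                                   tuple(int(s) for s in starts),
                                   OP_OVERLAP, False)
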