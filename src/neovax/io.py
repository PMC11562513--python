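"""Reading and writing the pipeline's plain-text interchange formats.

Everything is tab-separated tables or FASTA/GenBank via Biopython; a cohort
run writes one directory with all stages so any half of the pipeline can be
re-run from files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .construct import VaccineConstruct, construct_to_genbank
from .pipeline import CohortAnalysis, SyntheticCohort
from .report import report_to_json, report_to_markdown


def write_fasta(sequences: Mapping[str, str], path: Path | str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path | str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_variants(path: Path | str) -> pd.DataFrame:
    """Variant TSV: patient_id, protein_id, position (1-based), ref, alt,
    type (missense|frameshift), vaf, tpm, rna_alt_reads, driver_flag."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "protein_id": str})
    df["driver_flag"] = df["driver_flag"].astype(bool)
    if "planted_allele" not in df.columns:
        df["planted_allele"] = ""
    return df


def write_cohort(cohort: SyntheticCohort, outdir: Path | str) -> Path:
    """Write every artifact of a simulated cohort under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.proteome, out / "proteome.fasta")
    cohort.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    cohort.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    pd.DataFrame([(p, a) for p, al in cohort.hla.items() for a in al],
                 columns=["patient_id", "allele"]).to_csv(
        out / "hla.tsv", sep="\t", index=False)
    cohort.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)

    sel_rows = []
    for p, sel in cohort.selections.items():
        for rank, wid in enumerate(sel.windows, start=1):
            sel_rows.append((p, rank, wid, sel.relaxation_step, sel.status))
    pd.DataFrame(sel_rows, columns=["patient_id", "rank", "window_id",
                                    "relaxation_step", "status"]).to_csv(
        out / "selections.tsv", sep="\t", index=False)

    windows = {wid: w.mt_sequence for wid, w in cohort.windows.items()}
    write_fasta(windows, out / "windows_mt.fasta")
    write_constructs(cohort.constructs, out)

    panel_rows = []
    for wid, panel in cohort.panels.items():
        for i, (s, pep) in enumerate(zip(panel.starts, panel.peptides), start=1):
            panel_rows.append((wid, i, pep, s, len(pep)))
    pd.DataFrame(panel_rows, columns=["window_id", "peptide_index", "sequence",
                                      "start", "length"]).to_csv(
        out / "peptide_panels.tsv", sep="\t", index=False)

    cohort.elispot.to_csv(out / "elispot.tsv", sep="\t", index=False)
    cohort.ics.to_csv(out / "ics.tsv", sep="\t", index=False)
    cohort.clonotypes.to_csv(out / "clonotypes.tsv", sep="\t", index=False)
    cohort.followup.to_csv(out / "followup.tsv", sep="\t", index=False)

    truth = {
        "immunogenic_epitopes": sorted(list(t) for t in
                                       cohort.ground_truth.immunogenic_epitopes),
        "expanded_clonotypes": sorted(list(t) for t in
                                      cohort.ground_truth.expanded_clonotypes),
    }
    (out / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
    cfg = {"cohort": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in vars(cohort.config).items()}}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    return out


def write_constructs(constructs: Mapping[str, VaccineConstruct],
                     outdir: Path | str) -> None:
    out = Path(outdir)
    if not constructs:
        return
    write_fasta({p: c.protein_sequence for p, c in constructs.items()},
                out / "constructs_protein.fasta")
    write_fasta({p: c.dna_sequence for p, c in constructs.items()},
                out / "constructs_dna.fasta")
    records = [construct_to_genbank(c, name=p) for p, c in constructs.items()]
    SeqIO.write(records, str(out / "constructs.gb"), "genbank")


def write_analysis(analysis: CohortAnalysis, outdir: Path | str) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    analysis.calls.to_csv(out / "response_calls.tsv", sep="\t", index=False)
    analysis.responders.to_csv(out / "responders.tsv", sep="\t", index=False)
    analysis.ics_calls.to_csv(out / "ics_calls.tsv", sep="\t", index=False)
    if len(analysis.expansion):
        analysis.expansion.to_csv(out / "tcr_expansion.tsv", sep="\t", index=False)
    (out / "cohort_report.json").write_text(report_to_json(analysis.report))
    (out / "cohort_report.md").write_text(report_to_markdown(analysis.report))
    return out
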