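"""Peptide windows around protein-altering somatic variants.

Each missense variant is expanded into a mutant ~25-mer window (up to 12
residues flanking the substituted residue on each side) with its matched
wild-type sequence; frameshift variants yield a window of up to 12 upstream
residues plus the novel downstream tail, with no wild-type partner.  Minimal
8-11-mer mutant/wild-type epitope pairs are enumerated from every window for
each patient HLA allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

MISSENSE = "missense"
FRAMESHIFT = "frameshift"

DEFAULT_FLANK = 12
DEFAULT_MAX_WINDOW = 25
MINIMAL_LENGTHS = (8, 9, 10, 11)


class ReferenceMismatchError(ValueError):
    """Variant annotation disagrees with the reference protein sequence."""


@dataclass(frozen=True)
class SomaticVariant:
    """One protein-altering somatic mutation.

    ``position`` is 1-based.  For missense variants ``alt`` is the substituted
    residue; for frameshifts ``alt`` is the entire novel downstream peptide
    (optionally terminated by ``*``), which replaces the reference from
    ``position`` onward.
    """

    patient_id: str
    protein_id: str
    position: int
    ref: str
    alt: str
    variant_type: str = MISSENSE
    vaf: float = 0.5
    tpm: float = 10.0
    rna_alt_reads: int = 5
    driver_flag: bool = False

    def __post_init__(self) -> None:
        if self.variant_type not in (MISSENSE, FRAMESHIFT):
            raise ValueError(f"unknown variant type {self.variant_type!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"VAF must be in (0, 1], got {self.vaf}")

    @property
    def neoantigen_id(self) -> str:
        change = (f"{self.ref}{self.position}{self.alt}" if self.variant_type == MISSENSE
                  else f"{self.ref}{self.position}fs")
        return f"{self.patient_id}_{self.protein_id}_{change}"


@dataclass(frozen=True)
class PeptideWindow:
    """Mutant window with matched wild type (absent for frameshifts).

    ``mut_offset`` is the 0-based index of the substituted residue (missense)
    or of the first novel residue (frameshift) within ``mt_sequence``.
    """

    neoantigen_id: str
    patient_id: str
    mt_sequence: str
    wt_sequence: str | None
    mut_offset: int
    left_flank: int
    right_flank: int
    variant_type: str = MISSENSE

    def __post_init__(self) -> None:
        if len(self.mt_sequence) > DEFAULT_MAX_WINDOW:
            raise ValueError("window exceeds the 25-residue maximum")
        if self.variant_type == MISSENSE:
            if self.wt_sequence is None or len(self.wt_sequence) != len(self.mt_sequence):
                raise ValueError("missense window requires a matched-length WT sequence")
            if self.left_flank + 1 + self.right_flank != len(self.mt_sequence):
                raise ValueError("flanks inconsistent with window length")


@dataclass(frozen=True)
class MinimalEpitopePair:
    """A minimal 8-11-mer mutant peptide with its matched wild-type peptide
    (absent for frameshifts) for one HLA allele.

    ``mutation_pos_in_peptide`` is 1-based, or None for frameshift peptides.
    """

    mt_peptide: str
    wt_peptide: str | None
    allele: str
    window_id: str
    start_in_window: int
    mutation_pos_in_peptide: int | None


def apply_variant(protein_sequence: str, variant: SomaticVariant) -> str:
    """Apply one variant to the reference protein.

    Missense: single substitution, length preserved.  Frameshift: reference
    prefix up to the variant followed by the annotated novel tail, truncated
    at the first stop (``*``).
    """
    pos0 = variant.position - 1
    if pos0 >= len(protein_sequence):
        raise ReferenceMismatchError(
            f"position {variant.position} beyond protein {variant.protein_id} "
            f"({len(protein_sequence)} aa)")
    if protein_sequence[pos0] != variant.ref:
        raise ReferenceMismatchError(
            f"reference residue mismatch at {variant.protein_id}:{variant.position}: "
            f"annotation says {variant.ref!r}, reference has {protein_sequence[pos0]!r}")
    if variant.variant_type == MISSENSE:
        if len(variant.alt) != 1:
            raise ValueError("missense alt must be a single residue")
        return protein_sequence[:pos0] + variant.alt + protein_sequence[pos0 + 1:]
    tail = variant.alt.split("*", 1)[0]
    if not tail:
        raise ValueError("frameshift produces an empty novel peptide")
    return protein_sequence[:pos0] + tail


def extract_window(wt_protein: str, mt_protein: str, variant: SomaticVariant,
                   flank: int = DEFAULT_FLANK,
                   max_window: int = DEFAULT_MAX_WINDOW) -> PeptideWindow:
    """Cut the mutant window (and matched wild type for missense) around the
    variant: up to ``flank`` residues on each side, total length capped at
    ``max_window``."""
    pos0 = variant.position - 1
    left = min(flank, pos0)
    if variant.variant_type == MISSENSE:
        right = min(flank, len(wt_protein) - variant.position)
        mt_seq = mt_protein[pos0 - left: pos0 + right + 1]
        wt_seq = wt_protein[pos0 - left: pos0 + right + 1]
        return PeptideWindow(variant.neoantigen_id, variant.patient_id,
                             mt_seq, wt_seq, left, left, right, MISSENSE)
    # frameshift: upstream flank plus novel tail, capped at max_window total
    tail_len = min(len(mt_protein) - pos0, max_window - left)
    mt_seq = mt_protein[pos0 - left: pos0 + tail_len]
    return PeptideWindow(variant.neoantigen_id, variant.patient_id,
                         mt_seq, None, left, left, tail_len - 1, FRAMESHIFT)


def enumerate_minimal_epitopes(window: PeptideWindow,
                               alleles: Sequence[str],
                               lengths: Iterable[int] = MINIMAL_LENGTHS,
                               ) -> list[MinimalEpitopePair]:
    """All substrings of the requested lengths that overlap the mutated
    residue(s), crossed with every allele.

    For missense windows a substring must contain ``mut_offset`` and carries
    its matched wild-type substring; for frameshift windows it must overlap
    the novel tail (any position >= ``mut_offset``) and has no WT partner.
    A window shorter than every requested length yields an empty list.
    """
    pairs: list[MinimalEpitopePair] = []
    mt = window.mt_sequence
    for k in sorted(set(lengths)):
        if k > len(mt):
            continue
        for s in range(len(mt) - k + 1):
            if window.variant_type == MISSENSE:
                if not s <= window.mut_offset <= s + k - 1:
                    continue
                wt_pep = window.wt_sequence[s: s + k]
                mut_pos = window.mut_offset - s + 1
            else:
                if s + k - 1 < window.mut_offset:
                    continue
                wt_pep = None
                mut_pos = None
            for allele in alleles:
                pairs.append(MinimalEpitopePair(mt[s: s + k], wt_pep, allele,
                                                window.neoantigen_id, s, mut_pos))
    return pairs
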