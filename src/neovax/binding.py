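"""Deterministic toy MHC class I binding predictor.

Real neoantigen pipelines query an ensemble of trained binding predictors for
each candidate peptide/HLA pair.  This module provides a self-contained,
fully deterministic stand-in with the properties the downstream prioritization
logic needs: per-allele position weights, distinct "algorithms" that perturb
those weights so the ensemble median is non-degenerate, a constructible
strong-binder motif per allele that scores well below the conventional 500 nM
cutoff, and unrelated peptides that score far above it.

The score of a peptide is the mean positional weight under the allele's
9-column log-weight table (8/10/11-mers are mapped onto the 9 columns
anchor-aligned: N-terminal positions to columns 1-5, the 4 C-terminal
positions to columns 6-9).  The mean weight ``s`` in [0, 1] maps to
``IC50 = 50000 ** (1 - s)`` nM, so a perfect motif match scores ~1 nM and a
random peptide scores in the thousands.
"""

from __future__ import annotations

import zlib
from functools import lru_cache

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

PEPTIDE_LENGTHS = (8, 9, 10, 11)
IC50_CEILING = 50_000.0

#: anchor positions (1-based): position 2 and the C-terminus
DEFAULT_ANCHORS = frozenset({2, -1})


class PeptideError(ValueError):
    """Raised for peptides of invalid length or with non-canonical residues."""


def _stable_seed(*parts: object) -> int:
    """Deterministic 32-bit seed from string parts (independent of PYTHONHASHSEED)."""
    return zlib.crc32("|".join(str(p) for p in parts).encode())


def encode_peptide(peptide: str) -> np.ndarray:
    if len(peptide) not in PEPTIDE_LENGTHS:
        raise PeptideError(f"peptide length must be 8-11, got {len(peptide)!r}")
    try:
        return np.array([_AA_INDEX[aa] for aa in peptide], dtype=np.intp)
    except KeyError as exc:
        raise PeptideError(f"non-canonical residue {exc.args[0]!r} in {peptide!r}") from None


@lru_cache(maxsize=4096)
def position_columns(length: int) -> tuple[int, ...]:
    """Map 1-based peptide positions of an ``length``-mer to the 9 weight
    columns (0-based): N-terminal run to columns 0-4, last four residues to
    columns 5-8."""
    if length not in PEPTIDE_LENGTHS:
        raise PeptideError(f"peptide length must be 8-11, got {length}")
    cols = []
    for i in range(1, length + 1):
        if i <= length - 4:
            cols.append(min(i, 5) - 1)
        else:
            cols.append(9 - (length - i) - 1)
    return tuple(cols)


class ToyBindingPredictor:
    """Ensemble of ``n_algorithms`` deterministic per-allele scorers.

    Every allele gets a 9x20 weight table derived from a stable hash of its
    name: baseline weights U(0.02, 0.2), one consensus residue per column
    (never alanine) with weight 1.0, and alanine down-weighted to 0.05
    everywhere so a poly-A peptide is a reliable non-binder.  Each algorithm
    id applies a fixed +/-0.05 perturbation of the table, clipped to
    [0.01, 1.0].
    """

    def __init__(self, n_algorithms: int = 4):
        if n_algorithms < 1:
            raise ValueError("need at least one algorithm")
        self.n_algorithms = n_algorithms

    @property
    def algorithms(self) -> list[str]:
        return [f"algo{i + 1}" for i in range(self.n_algorithms)]

    @lru_cache(maxsize=512)
    def base_weights(self, allele: str) -> np.ndarray:
        rng = np.random.default_rng(_stable_seed("allele", allele))
        w = rng.uniform(0.02, 0.2, size=(9, 20))
        w[:, _AA_INDEX["A"]] = 0.05
        for col in range(9):
            consensus = rng.integers(1, 20)  # index 0 is A; excluded
            w[col, consensus] = 1.0
        w.setflags(write=False)
        return w

    @lru_cache(maxsize=2048)
    def weights(self, allele: str, algorithm: str) -> np.ndarray:
        if algorithm not in self.algorithms:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        rng = np.random.default_rng(_stable_seed("algo", allele, algorithm))
        w = np.clip(self.base_weights(allele) + rng.uniform(-0.05, 0.05, size=(9, 20)),
                    0.01, 1.0)
        w.setflags(write=False)
        return w

    @lru_cache(maxsize=512)
    def consensus_motif(self, allele: str) -> str:
        """The allele's designated strong-binder 9-mer (argmax residue per column)."""
        w = self.base_weights(allele)
        return "".join(AMINO_ACIDS[i] for i in np.argmax(w, axis=1))

    def predict(self, peptide: str, allele: str, algorithm: str) -> float:
        """Pseudo-IC50 in nM for one peptide/allele/algorithm triple."""
        idx = encode_peptide(peptide)
        cols = np.array(position_columns(len(peptide)), dtype=np.intp)
        s = self.weights(allele, algorithm)[cols, idx].mean()
        return float(IC50_CEILING ** (1.0 - s))

    def predict_batch(self, peptides: list[str], allele: str, algorithm: str) -> np.ndarray:
        """Vectorized ``predict`` for same-length peptides."""
        if not peptides:
            return np.empty(0)
        length = len(peptides[0])
        if any(len(p) != length for p in peptides):
            raise PeptideError("predict_batch requires same-length peptides")
        idx = np.stack([encode_peptide(p) for p in peptides])
        cols = np.array(position_columns(length), dtype=np.intp)
        s = self.weights(allele, algorithm)[cols[None, :], idx].mean(axis=1)
        return IC50_CEILING ** (1.0 - s)

    def predict_ensemble(self, peptide: str, allele: str) -> list[float]:
        """IC50 under every algorithm, in algorithm order."""
        return [self.predict(peptide, allele, a) for a in self.algorithms]


def allele_pool(n: int = 12) -> list[str]:
    """Synthetic HLA class I allele names, four per locus A/B/C."""
    loci = ["A", "B", "C"]
    return [f"HLA-{loci[i % 3]}*{i // 3 + 1:02d}:01" for i in range(n)]
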