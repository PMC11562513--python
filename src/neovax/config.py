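"""Configuration objects for cohort simulation, prioritization and response calling.

All tunable thresholds of the pipeline live here so that a single YAML file can
drive an end-to-end run.  Defaults reproduce the study conditions: an 18-patient
cohort with a median of ~21.5 expressed protein-altering mutations per patient,
~97% missense variants, 4-20 vaccinated epitopes per patient, ~23% of vaccinated
epitopes truly immunogenic, and 2/18 recurrences over ~3 years of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic trial cohort.

    Proportions are in [0, 1]; counts are positive integers.  An identical
    config + seed yields byte-identical output tables.
    """

    n_patients: int = 18
    n_proteins: int = 60
    protein_length_range: tuple[int, int] = (200, 500)
    mutations_per_patient_median: float = 21.5
    missense_fraction: float = 0.97
    #: fraction of variants engineered to create a strong-binding mutant 9-mer
    binder_fraction: float = 0.3
    #: fraction of vaccinated epitopes that are truly immunogenic (ground truth)
    immunogenic_fraction: float = 0.23
    #: negative-binomial dispersion (size) for ELISpot well counts; 50 gives
    #: ~15% replicate CV at high counts, typical of ELISpot duplicate wells
    elispot_noise: float = 50.0
    #: SD of ICS percent-positive readouts
    ics_noise: float = 0.3
    n_clonotypes: int = 1000
    #: sequencing depth of each clonotype table
    clonotype_depth: int = 10_000
    expansion_factor: float = 20.0
    recurrence_rate: float = 2.0 / 18.0
    n_controls: int = 60
    #: control-arm exponential hazard per month (~50% RFS at 36 months)
    control_hazard: float = 0.01925
    n_alleles_per_patient: int = 6
    n_algorithms: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missense_fraction", "binder_fraction", "immunogenic_fraction",
                     "recurrence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_patients", "n_proteins", "n_clonotypes", "clonotype_depth",
                     "n_alleles_per_patient", "n_algorithms"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v}")
        lo, hi = self.protein_length_range
        if lo < 30 or hi < lo:
            raise ConfigError(
                f"protein_length_range must satisfy 30 <= lo <= hi, got {self.protein_length_range}")
        if self.mutations_per_patient_median <= 0:
            raise ConfigError("mutations_per_patient_median must be positive")
        if self.elispot_noise <= 0 or self.ics_noise < 0:
            raise ConfigError("noise parameters must be positive")


@dataclass
class PrioritizationThresholds:
    """Filter and selection thresholds for epitope prioritization.

    ``ic50_max`` is the conventional 500 nM binder cutoff on the ensemble
    median mutant IC50.  Expression requires transcript TPM > 0 and at least
    ``min_rna_alt_reads`` mutant-supporting RNA reads.  Candidates whose
    missense mutation sits on an HLA anchor position must additionally show a
    wild-type/mutant fold change > ``min_anchor_fold``.
    """

    ic50_max: float = 500.0
    min_rna_alt_reads: int = 1
    min_anchor_fold: float = 1.0
    clonality_ratio: float = 0.5
    min_select: int = 4
    max_select: int = 20
    #: optional minimum sequencing coverage filter; disabled by default
    min_coverage: int | None = None

    def relaxed(self, step: int) -> "PrioritizationThresholds":
        """Relaxation schedule used when a vaccine has too few passing epitopes.

        Step 1 doubles the IC50 cutoff; step 2 additionally drops the
        mutant-allele expression requirement.
        """
        t = PrioritizationThresholds(**asdict(self))
        if step >= 1:
            t.ic50_max = self.ic50_max * 2
        if step >= 2:
            t.min_rna_alt_reads = 0
        return t


@dataclass
class CallerThresholds:
    """ELISpot / ICS response-calling rules.

    Screening positivity requires a background-subtracted post-vaccination mean
    of at least ``min_sfc`` SFC/1e6 and at least ``min_fold`` times the
    (floored) pre-vaccination mean.  Confirmation is a one-sided Welch t-test
    at ``alpha``.  The ICS strict rule is post >= 2x pre and post >= 1%.
    """

    min_sfc: float = 50.0
    min_fold: float = 2.0
    alpha: float = 0.05
    welch: bool = True
    ics_min_fold: float = 2.0
    ics_min_percent: float = 1.0
    dominance_fraction: float = 0.6


@dataclass
class ExpansionConfig:
    """Clonotype-expansion test settings: exact one-sided 2x2 test,
    Benjamini-Hochberg across clonotypes, and a fold-change floor."""

    pseudocount: float = 0.5
    alpha: float = 0.05
    min_fold: float = 4.0


_SECTIONS = {
    "cohort": CohortConfig,
    "prioritization": PrioritizationThresholds,
    "caller": CallerThresholds,
    "expansion": ExpansionConfig,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config with optional sections cohort / prioritization /
    caller / expansion; missing sections take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        values = dict(raw.get(section, {}))
        if section == "cohort" and "protein_length_range" in values:
            values["protein_length_range"] = tuple(values["protein_length_range"])
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
        out[section] = cls(**values)
    return out
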