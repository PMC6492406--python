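"""Validated configuration objects for the pipeline and the cohort simulator.

Defaults mirror the parameters used throughout HLA class I immunopeptidomics
practice: 8-11mer ligands, a 5% PSM-level FDR on eluted-ligand identifications,
tryptic digestion with at most two missed cleavages, and a tumor mutational
burden expressed in non-synonymous variants per megabase of callable exome.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline parameters.

    Attributes
    ----------
    min_length, max_length:
        Peptide window lengths for the mutated peptide search space and the
        ligand length filter (HLA class I ligands are canonically 8-11 residues).
    q_threshold:
        PSM FDR (q-value) cutoff applied to eluted-ligand lists.
    binder_threshold:
        Relative position-weight-matrix score (score / max attainable score)
        above which a peptide is called an HLA binder.
    max_missed_cleavages, proline_rule:
        Tryptic digestion settings; ``proline_rule`` suppresses cleavage of
        K/R-P bonds (conventional trypsin specificity).
    min_alt_reads, min_fpkm:
        RNA-evidence thresholds: a non-synonymous variant is *expressed* when
        its alt-supporting RNA depth and transcript FPKM reach these values
        (FPKM is compared strictly when ``min_fpkm`` is 0, i.e. fpkm > 0).
    callable_region_mb:
        Callable exome size used to convert variant counts to TMB.
    shotgun_min_len, shotgun_max_len:
        Detectability window applied when matching tryptic peptides against
        shotgun data.
    """

    min_length: int = 8
    max_length: int = 11
    q_threshold: float = 0.05
    binder_threshold: float = 0.5
    max_missed_cleavages: int = 2
    proline_rule: bool = True
    min_alt_reads: int = 1
    min_fpkm: float = 0.0
    callable_region_mb: float = 35.0
    shotgun_min_len: int = 6
    shotgun_max_len: int = 30
    il_equivalent: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        _check(1 <= self.min_length <= self.max_length, "invalid length range")
        _check(0.0 <= self.q_threshold <= 1.0, "q_threshold must be in [0,1]")
        _check(self.max_missed_cleavages >= 0, "max_missed_cleavages must be >= 0")
        _check(self.min_alt_reads >= 0, "min_alt_reads must be >= 0")
        _check(self.min_fpkm >= 0, "min_fpkm must be >= 0")
        _check(self.callable_region_mb > 0, "callable_region_mb must be > 0")
        _check(self.shotgun_min_len <= self.shotgun_max_len, "invalid shotgun length window")

    @property
    def length_range(self) -> range:
        return range(self.min_length, self.max_length + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Parameters of the synthetic cohort generator.

    The defaults emulate a resectable hepatocellular-carcinoma-like cohort:
    TMB near 1.9 non-synonymous variants per megabase over a ~35 Mb callable
    exome (hence ~66 Var^ns and ~150 total Var per patient), RNA-level
    evidence for ~44% of non-synonymous variants, and eluted-ligand lists in
    the low-hundreds-to-thousands range per tissue. ``ligand_list_size_mean``
    defaults to 300 rather than the ~1400 seen in deep immunopeptidome
    datasets to keep simulated cohorts fast; the planting and recovery logic
    is independent of list size.
    """

    n_patients: int = 16
    proteome_size: int = 200
    protein_length_mean: float = 450.0
    protein_length_sd: float = 150.0
    min_protein_length: int = 30
    tmb_mean: float = 1.89
    tmb_sd: float = 0.49
    callable_region_mb: float = 35.0
    nonsyn_fraction: float = 0.44
    rna_evidence_rate: float = 0.44
    planted_nelig_per_patient: int = 2
    planted_wtlig_per_patient: int = 1
    ligand_list_size_mean: float = 300.0
    ligand_list_size_sd: float = 60.0
    ligand_shared_fraction: float = 0.5
    shotgun_coverage_rate: float = 0.3
    n_alleles: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nonsyn_fraction", "rna_evidence_rate", "ligand_shared_fraction",
                     "shotgun_coverage_rate"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0,1]")
        for name in ("n_patients", "proteome_size", "planted_nelig_per_patient",
                     "planted_wtlig_per_patient", "n_alleles"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        _check(self.proteome_size >= 1 or self.n_patients == 0, "proteome_size must be >= 1")
        _check(self.min_protein_length >= 30, "min_protein_length must be >= 30")
        _check(self.tmb_mean >= 0 and self.callable_region_mb > 0, "invalid TMB parameters")
        _check(1 <= self.n_alleles <= 6, "n_alleles must be in 1..6")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticCohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
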