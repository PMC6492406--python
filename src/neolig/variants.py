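"""Somatic variant semantics: classification, expression evidence, TMB, recurrence.

Terminology follows the standard proteogenomics tiering: Var (all somatic
variants), Var^ns (non-synonymous, i.e. protein-altering), Var^exp (Var^ns with
RNA-level evidence). TMB is Var^ns per megabase of callable exome.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

_DNA = set("ACGTN")

VAR_CLASSES = ("SNV", "insertion", "deletion", "frameshift")


@dataclass(frozen=True)
class ProteinChange:
    """Protein-level consequence: 1-based position, reference and alternate residues.

    For frameshifts ``alt_aa`` may be empty (the new tail is derived from the
    CDS, not from the annotation).
    """

    protein_pos: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValueError("protein_pos is 1-based and must be >= 1")

    @property
    def hgvs_like(self) -> str:
        return f"{self.ref_aa}{self.protein_pos}{self.alt_aa}"


@dataclass
class Variant:
    """A somatic alteration with DNA/RNA evidence and protein annotation."""

    patient_id: str
    chrom: str
    genomic_pos: int
    ref_allele: str
    alt_allele: str
    gene: str = ""
    transcript_id: str = ""
    protein_id: str = ""
    protein_change: Optional[ProteinChange] = None
    var_class: str = ""
    is_nonsynonymous: bool = False
    rna_depth: int = 0
    rna_alt_depth: int = 0
    fpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.rna_depth < 0 or self.rna_alt_depth < 0:
            raise ValueError("read depths must be >= 0")
        if not self.var_class:
            self.var_class, self.is_nonsynonymous = classify_variant(
                self.ref_allele, self.alt_allele, self.protein_change
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.genomic_pos, self.ref_allele, self.alt_allele)

    @property
    def is_hla_region(self) -> bool:
        # flagged, never excluded: variant calls in the polymorphic HLA locus
        # are potential artifacts
        return self.gene.upper().startswith("HLA-")

    @property
    def change_label(self) -> str:
        if self.protein_change is None:
            return "fs" if self.var_class == "frameshift" else "na"
        return self.protein_change.hgvs_like


def _validate_allele(allele: str) -> None:
    if not allele or not set(allele.upper()) <= _DNA:
        raise ValueError(f"invalid DNA allele: {allele!r}")


def classify_variant(
    ref_allele: str,
    alt_allele: str,
    protein_change: Optional[ProteinChange] = None,
) -> tuple[str, bool]:
    """Classify a variant into SNV / insertion / deletion / frameshift.

    A variant is a frameshift when the indel length is not a multiple of
    three; it is non-synonymous when it is a frameshift or its protein change
    alters the residue. The four classes partition all inputs.
    """
    _validate_allele(ref_allele)
    _validate_allele(alt_allele)
    lr, la = len(ref_allele), len(alt_allele)
    if lr == 1 and la == 1:
        var_class = "SNV"
    elif abs(lr - la) % 3 != 0:
        var_class = "frameshift"
    elif la > lr:
        var_class = "insertion"
    else:
        var_class = "deletion"
    if var_class == "frameshift":
        nonsyn = True
    elif protein_change is None:
        nonsyn = False
    else:
        nonsyn = protein_change.ref_aa != protein_change.alt_aa
    return var_class, nonsyn


def is_expressed(variant: Variant, min_alt_reads: int = 1, min_fpkm: float = 0.0) -> bool:
    """Var^exp rule: alt-supporting RNA reads plus transcript expression.

    True iff ``rna_alt_depth >= min_alt_reads`` and the FPKM passes
    (strictly > 0 when ``min_fpkm`` is 0, else >= ``min_fpkm``).
    """
    if min_alt_reads < 0 or min_fpkm < 0:
        raise ValueError("thresholds must be non-negative")
    if not variant.is_nonsynonymous:
        raise ValueError("expression evidence is defined for non-synonymous variants")
    fpkm_ok = variant.fpkm > 0.0 if min_fpkm == 0.0 else variant.fpkm >= min_fpkm
    return variant.rna_alt_depth >= min_alt_reads and fpkm_ok


def compute_tmb(n_varns: int, callable_region_mb: float) -> float:
    """Tumor mutational burden: non-synonymous variants per callable megabase."""
    if callable_region_mb <= 0:
        raise ValueError("callable_region_mb must be > 0")
    return n_varns / callable_region_mb


@dataclass
class RecurrenceReport:
    """Genes shared across patients and identically recurring genomic variants."""

    shared_genes: pd.DataFrame      # columns: gene, n_patients
    recurrent_variants: pd.DataFrame  # columns: chrom, pos, ref, alt, n_patients


def recurrence_analysis(variants: Sequence[Variant], min_patients: int = 3) -> RecurrenceReport:
    """Find genes mutated in >= min_patients distinct patients and variants
    recurring at identical genomic coordinates (chrom, pos, ref, alt)."""
    if not variants:
        raise ValueError("cohort variant table is empty")
    rows = [
        {
            "patient": v.patient_id, "gene": v.gene, "chrom": v.chrom,
            "pos": v.genomic_pos, "ref": v.ref_allele, "alt": v.alt_allele,
        }
        for v in variants
    ]
    df = pd.DataFrame(rows)
    gene_counts = (
        df[df["gene"] != ""].groupby("gene")["patient"].nunique().reset_index(name="n_patients")
    )
    shared = gene_counts[gene_counts["n_patients"] >= min_patients].sort_values(
        ["n_patients", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    pos_counts = (
        df.groupby(["chrom", "pos", "ref", "alt"])["patient"].nunique().reset_index(name="n_patients")
    )
    recurrent = pos_counts[pos_counts["n_patients"] >= min_patients].sort_values(
        ["n_patients", "chrom", "pos"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return RecurrenceReport(shared_genes=shared, recurrent_variants=recurrent)


def check_cohort_unique(variants: Iterable[Variant]) -> None:
    """Enforce (patient, chrom, pos, ref, alt) uniqueness across a cohort table."""
    seen = set()
    for v in variants:
        k = (v.patient_id,) + v.key
        if k in seen:
            raise ValueError(f"duplicate cohort variant: {k}")
        seen.add(k)
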