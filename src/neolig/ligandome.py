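"""Eluted HLA-ligand lists: FDR/length filtering, tumor/normal overlap, and
screening against cancer-testis antigens (CTA)."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd


@dataclass
class LigandRecord:
    peptide: str
    q_value: float
    source_protein_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.peptide = self.peptide.upper()
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q-value must be in [0,1]")


@dataclass
class LigandomeSample:
    """Tissue-labeled list of eluted HLA class I peptides with q-values."""

    patient_id: str
    tissue: str  # "tumor" or "non_malignant"
    records: list[LigandRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "non_malignant"):
            raise ValueError(f"unknown tissue label: {self.tissue!r}")

    @property
    def peptides(self) -> set[str]:
        return {r.peptide for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


def filter_ligands(
    sample: LigandomeSample,
    q_threshold: float = 0.05,
    length_range: tuple[int, int] = (8, 11),
) -> LigandomeSample:
    """Retain records with q <= threshold and length within the closed range;
    deduplicate identical peptides keeping the best (smallest) q. Idempotent."""
    lo, hi = length_range
    if lo > hi:
        raise ValueError("inverted length range")
    best: dict[str, LigandRecord] = {}
    for r in sample.records:
        if r.q_value <= q_threshold and lo <= len(r.peptide) <= hi:
            prev = best.get(r.peptide)
            if prev is None or r.q_value < prev.q_value:
                best[r.peptide] = r
    return LigandomeSample(
        patient_id=sample.patient_id,
        tissue=sample.tissue,
        records=[best[p] for p in sorted(best)],
    )


def overlap_fraction(
    tumor: LigandomeSample,
    normal: LigandomeSample,
    mode: str = "tumor",
) -> Optional[float]:
    """Fraction of peptides shared between matched tumor and non-malignant
    tissue. Mode "tumor": |T ∩ N| / |T|; mode "union": |T ∩ N| / |T ∪ N|.
    Returns None on an empty denominator."""
    t, n = tumor.peptides, normal.peptides
    if mode == "tumor":
        denom = len(t)
    elif mode == "union":
        denom = len(t | n)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    if denom == 0:
        return None
    return len(t & n) / denom


def cta_screen(
    samples: Sequence[LigandomeSample],
    cta_list: pd.DataFrame,
) -> pd.DataFrame:
    """Screen ligand lists against a cancer-testis antigen catalogue.

    ``cta_list`` maps accession -> antigen name and family; ligands whose
    source accession is catalogued are reported, and antigen counting
    collapses family members (e.g. the SSX paralogues) into one antigen via
    the family column.

    Returns a table with columns peptide, accessions, antigen, sample;
    ``antigen`` is the family name when one is defined, else the
    antigen name.
    """
    required = {"accession", "antigen"}
    if not required <= set(cta_list.columns):
        raise ValueError(f"CTA list must have columns {sorted(required)}")
    has_family = "family" in cta_list.columns
    info: dict[str, tuple[str, str]] = {}
    for _, row in cta_list.iterrows():
        fam = str(row["family"]) if has_family and pd.notna(row.get("family")) \
            and str(row.get("family")).strip() else str(row["antigen"])
        info[str(row["accession"])] = (str(row["antigen"]), fam)

    rows = []
    for sample in samples:
        for rec in sample.records:
            if not rec.source_protein_ids:
                raise ValueError("ligand records must carry source-protein accessions")
            hits = [acc for acc in rec.source_protein_ids if acc in info]
            if not hits:
                continue
            collapsed = sorted({info[a][1] for a in hits})
            rows.append({
                "peptide": rec.peptide,
                "accessions": ";".join(hits),
                "antigen": ";".join(collapsed),
                "sample": sample.patient_id,
                "tissue": sample.tissue,
            })
    return pd.DataFrame(rows, columns=["peptide", "accessions", "antigen", "sample", "tissue"])


def cta_summary(screen: pd.DataFrame) -> tuple[int, int]:
    """(distinct CTA ligand peptides, distinct antigens after family collapse)."""
    if screen.empty:
        return (0, 0)
    peptides = screen["peptide"].nunique()
    antigens = {a for cell in screen["antigen"] for a in str(cell).split(";")}
    return (peptides, len(antigens))
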