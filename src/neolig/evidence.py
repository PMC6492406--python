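"""Evidence tiering: annotate candidates with RNA / shotgun / ligandome
evidence and summarize the per-patient waterfall.

Tier semantics. PNE: predicted HLA-binding mutated peptide. PNE^exp: its
source variant has RNA-level evidence (Var^exp). PNE^prot: shotgun proteome
evidence for the source protein (headline level) or for the mutant peptide
itself. NE^lig: the mutated sequence was itself eluted from the patient's
tumor HLA class I ligandome. WT^lig: the wild-type counterpart window was
eluted in any of the patient's tissues. Nesting NE^lig ⊆ PNE and
PNE^exp ⊆ PNE holds by construction and is enforced when summarizing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .ligandome import LigandomeSample
from .variants import Variant, is_expressed

TIER_ORDER = ("Var", "Var_ns", "Var_exp", "PSS", "PNE", "PNE_exp", "PNE_prot", "NE_lig")


@dataclass
class TierSummary:
    """Per-patient unique-peptide counts along the evidence waterfall plus
    WT^lig detections as (peptide, tissue) pairs."""

    patient_id: str
    n_var: int = 0
    n_var_ns: int = 0
    n_var_exp: int = 0
    n_pss: int = 0
    n_pne: int = 0
    n_pne_exp: int = 0
    n_pne_prot: int = 0
    n_ne_lig: int = 0
    wt_lig_detections: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = [self.n_var, self.n_var_ns, self.n_var_exp, self.n_pss,
                  self.n_pne, self.n_pne_exp, self.n_pne_prot, self.n_ne_lig]
        if any(c < 0 for c in counts):
            raise ValueError("tier counts must be >= 0")
        if self.n_ne_lig > self.n_pne or self.n_pne_exp > self.n_pne or self.n_pne > self.n_pss:
            raise ValueError("tier nesting violated")

    def as_dict(self) -> dict:
        return {
            "patient": self.patient_id, "Var": self.n_var, "Var_ns": self.n_var_ns,
            "Var_exp": self.n_var_exp, "PSS": self.n_pss, "PNE": self.n_pne,
            "PNE_exp": self.n_pne_exp, "PNE_prot": self.n_pne_prot,
            "NE_lig": self.n_ne_lig,
            "WT_lig": ";".join(f"{p}@{t}" for p, t in self.wt_lig_detections),
        }


def annotate_rna_tier(
    candidates: Sequence,
    min_alt_reads: int = 1,
    min_fpkm: float = 0.0,
) -> None:
    """Flag a candidate PNE^exp iff its source variant is Var^exp."""
    for cand in candidates:
        v = cand.source_variant
        if v is None:
            raise ValueError(f"candidate {cand.sequence} has no source variant")
        if is_expressed(v, min_alt_reads, min_fpkm):
            cand.tier_flags.add("PNE_exp")


def annotate_ligandome_tier(
    candidates: Sequence,
    samples: Sequence[LigandomeSample],
    il_equivalent: bool = False,
) -> None:
    """Flag NE^lig / WT^lig by exact string match against pre-filtered eluted
    lists. NE^lig requires the mutated sequence in the patient's *tumor* list;
    WT^lig matches the wild-type counterpart in either tissue, recorded with
    its tissue label. ``il_equivalent`` collapses I/L (MS indistinguishability)
    before matching; off by default."""
    def norm(p: str) -> str:
        p = p.upper()
        return p.replace("I", "L") if il_equivalent else p

    by_patient: dict[str, list[LigandomeSample]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)

    for cand in candidates:
        for sample in by_patient.get(cand.patient_id, []):
            peptides = {norm(p) for p in sample.peptides}
            if sample.tissue == "tumor" and norm(cand.sequence) in peptides:
                cand.tier_flags.add("NE_lig")
            wt = cand.wt_counterpart
            if wt and norm(wt) in peptides:
                cand.tier_flags.add("WT_lig")
                det = getattr(cand, "wt_lig_tissues", set())
                det.add(sample.tissue)
                cand.wt_lig_tissues = det


def summarize_tiers(
    patient_id: str,
    variants: Sequence[Variant],
    pss_candidates: Sequence,
    min_alt_reads: int = 1,
    min_fpkm: float = 0.0,
) -> TierSummary:
    """Count unique peptide sequences per tier and enforce nesting.

    A candidate carrying NE^lig without PNE indicates inconsistent upstream
    annotation and raises.
    """
    n_var = len(variants)
    varns = [v for v in variants if v.is_nonsynonymous]
    n_var_exp = sum(is_expressed(v, min_alt_reads, min_fpkm) for v in varns)

    def tier_set(flag: str) -> set[str]:
        return {c.sequence for c in pss_candidates if flag in c.tier_flags}

    pne = tier_set("PNE")
    ne_lig = tier_set("NE_lig")
    pne_exp = tier_set("PNE_exp") & pne
    if not ne_lig <= pne:
        raise ValueError("inconsistent flags: NE_lig candidate outside PNE")
    wt_dets = sorted({
        (c.wt_counterpart, t)
        for c in pss_candidates if "WT_lig" in c.tier_flags
        for t in getattr(c, "wt_lig_tissues", set())
    })
    return TierSummary(
        patient_id=patient_id,
        n_var=n_var,
        n_var_ns=len(varns),
        n_var_exp=n_var_exp,
        n_pss=len({c.sequence for c in pss_candidates}),
        n_pne=len(pne),
        n_pne_exp=len(pne_exp),
        n_pne_prot=len(tier_set("PNE_prot") & pne),
        n_ne_lig=len(ne_lig),
        wt_lig_detections=wt_dets,
    )


def summaries_to_frame(summaries: Sequence[TierSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
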