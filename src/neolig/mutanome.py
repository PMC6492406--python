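"""Apply protein-level variant consequences and export the personalized search
database (reference proteome + patient-specific mutated proteins)."""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .variants import Variant

log = logging.getLogger(__name__)

AMBIGUOUS_RESIDUES = set("UBZX")


@dataclass
class MutatedProtein:
    """Wild-type/mutant sequence pair with the affected 1-based closed interval
    of mutant-sequence positions that differ from wild type."""

    protein_id: str
    wt_sequence: str
    mut_sequence: str
    affected_start: int
    affected_end: int
    source_variant: Variant

    def __post_init__(self) -> None:
        if "*" in self.wt_sequence or "*" in self.mut_sequence:
            raise ValueError("sequences must not contain internal stop symbols")
        if not (1 <= self.affected_start <= self.affected_end <= len(self.mut_sequence)):
            raise ValueError("affected interval out of bounds")

    @property
    def affected_interval(self) -> tuple[int, int]:
        return (self.affected_start, self.affected_end)

    @property
    def mutant_id(self) -> str:
        v = self.source_variant
        return f"{self.protein_id}|{v.patient_id}|{v.change_label}"


class AnnotationMismatchError(ValueError):
    """The annotated reference residue disagrees with the supplied sequence —
    the variant annotation and the proteome are incoherent."""


def apply_variant(
    wt_sequence: str,
    variant: Variant,
    cds: Optional[str] = None,
    cds_variant_pos: Optional[int] = None,
) -> Optional[MutatedProtein]:
    """Build the mutated protein for a non-synonymous variant.

    SNV and in-frame indels are applied at protein level from the annotated
    ``protein_change``. Frameshifts require the coding sequence plus the
    1-based CDS position of the edit; the mutant tail is translated with the
    standard genetic code to the first stop (stop excluded). A frameshift that
    stops at the first altered codon yields no novel residues; the variant is
    dropped with a warning and ``None`` is returned.
    """
    wt_sequence = wt_sequence.upper()
    pc = variant.protein_change

    if variant.var_class == "frameshift":
        return _apply_frameshift(wt_sequence, variant, cds, cds_variant_pos)

    if pc is None or not variant.is_nonsynonymous:
        raise ValueError("synonymous or unannotated variant must not reach the mutanome")

    pos = pc.protein_pos
    ref_aa, alt_aa = pc.ref_aa.upper(), pc.alt_aa.upper()
    if pos + len(ref_aa) - 1 > len(wt_sequence):
        raise AnnotationMismatchError(
            f"{variant.key}: position {pos} beyond protein of length {len(wt_sequence)}"
        )
    observed = wt_sequence[pos - 1 : pos - 1 + len(ref_aa)] if ref_aa else ""
    if observed != ref_aa:
        raise AnnotationMismatchError(
            f"{variant.key}: annotated ref {ref_aa!r} != sequence {observed!r} at {pos}"
        )

    if "*" in alt_aa:  # stop gain: truncation introduces no novel residues
        log.warning("stop-gain variant %s yields a truncated protein; no mutated "
                    "windows are generated", variant.key)
        return None

    mut = wt_sequence[: pos - 1] + alt_aa + wt_sequence[pos - 1 + len(ref_aa):]
    if alt_aa:
        start, end = pos, pos + len(alt_aa) - 1
    else:  # clean deletion: flag the junction residue (clipped to bounds)
        start = max(1, min(pos, len(mut)))
        end = start
    return MutatedProtein(
        protein_id=variant.protein_id or variant.gene,
        wt_sequence=wt_sequence,
        mut_sequence=mut,
        affected_start=start,
        affected_end=end,
        source_variant=variant,
    )


def _apply_frameshift(
    wt_sequence: str,
    variant: Variant,
    cds: Optional[str],
    cds_variant_pos: Optional[int],
) -> Optional[MutatedProtein]:
    if cds is None or cds_variant_pos is None:
        raise ValueError(f"{variant.key}: frameshift requires a CDS and the CDS edit position")
    cds = cds.upper()
    p = cds_variant_pos - 1
    ref, alt = variant.ref_allele.upper(), variant.alt_allele.upper()
    if cds[p : p + len(ref)] != ref:
        raise AnnotationMismatchError(f"{variant.key}: CDS does not carry the reference allele")
    mut_cds = cds[:p] + alt + cds[p + len(ref):]
    mut_prot = _translate_to_stop(mut_cds)
    first_diff = _first_difference(wt_sequence, mut_prot)
    if first_diff is None or first_diff >= len(mut_prot):
        log.warning("frameshift %s stops at the first altered codon; variant dropped",
                    variant.key)
        return None
    return MutatedProtein(
        protein_id=variant.protein_id or variant.gene,
        wt_sequence=wt_sequence,
        mut_sequence=mut_prot,
        affected_start=first_diff + 1,
        affected_end=len(mut_prot),
        source_variant=variant,
    )


def _translate_to_stop(cds: str) -> str:
    n = len(cds) - len(cds) % 3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial-codon warnings on odd tails
        aa = str(Seq(cds[:n]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def _first_difference(a: str, b: str) -> Optional[int]:
    for i in range(min(len(a), len(b))):
        if a[i] != b[i]:
            return i
    return min(len(a), len(b)) if len(a) != len(b) else None


def revert_snv(mut: MutatedProtein) -> str:
    """Revert an SNV-derived mutant back to wild type (consistency check)."""
    pc = mut.source_variant.protein_change
    if pc is None or mut.source_variant.var_class != "SNV":
        raise ValueError("revert is defined for SNVs only")
    i = pc.protein_pos - 1
    return mut.mut_sequence[:i] + pc.ref_aa + mut.mut_sequence[i + 1:]


def build_personalized_fasta(
    reference_records: Sequence[tuple[str, str]],
    mutated_proteins: Sequence[MutatedProtein],
) -> list[tuple[str, str]]:
    """Reference proteome records followed by one record per mutated protein,
    with the stable mutant header ``<protein_id>|<patient>|<change>``."""
    out = [(rid, seq.upper()) for rid, seq in reference_records]
    seen = {rid for rid, _ in out}
    for mp in mutated_proteins:
        mid = mp.mutant_id
        if mid in seen:
            raise ValueError(f"duplicate mutant record ID: {mid}")
        seen.add(mid)
        out.append((mid, mp.mut_sequence))
    return out
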