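"""Mutated peptide search space (PSS): sliding windows over affected positions,
wild-type counterparts, and exclusion of peptides contained in reference proteins.

For an interior single substitution with lengths 8-11 the window count is the
closed form sum(L for L in 8..11) = 38; clipping at protein termini only
reduces it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .mutanome import AMBIGUOUS_RESIDUES, MutatedProtein
from .variants import Variant


@dataclass
class PeptideCandidate:
    """An 8-11mer from the mutated search space with source bookkeeping.

    ``mut_offsets`` are the 1-based positions of mutated residues within the
    peptide; ``wt_counterpart`` is the same-coordinate wild-type window (SNV
    only — indel/frameshift peptides have no positional counterpart).
    ``sources`` collects every (protein, variant, start) that yields the same
    sequence, so duplicate sequences are counted once per patient.
    """

    sequence: str
    patient_id: str
    source_protein: str
    source_variant: Variant
    start: int  # 1-based start in the mutant sequence
    mut_offsets: tuple[int, ...]
    wt_counterpart: Optional[str] = None
    binding_records: list = field(default_factory=list)
    tier_flags: set = field(default_factory=set)
    sources: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.mut_offsets:
            raise ValueError("candidate must overlap at least one mutated position")
        if not all(1 <= o <= len(self.sequence) for o in self.mut_offsets):
            raise ValueError("mut_offsets out of peptide bounds")
        if not self.sources:
            self.sources = [(self.source_protein, self.source_variant.key, self.start)]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_binder(self) -> bool:
        return any(r.is_binder for r in self.binding_records)


def generate_windows(
    mut: MutatedProtein,
    length_range: Iterable[int] = range(8, 12),
) -> list[PeptideCandidate]:
    """Slide windows of each length over the affected mutated positions.

    For each length L, every L-window of the mutant sequence overlapping the
    affected interval is emitted, clipped to the sequence bounds. Windows
    containing ambiguous residues (U/B/Z/X) are dropped. Identical sequences
    are collapsed with multi-source bookkeeping.
    """
    seq = mut.mut_sequence
    a, b = mut.affected_interval
    by_seq: dict[str, PeptideCandidate] = {}
    for L in length_range:
        if len(seq) < L:
            continue
        lo = max(1, a - L + 1)
        hi = min(len(seq) - L + 1, b)
        for start in range(lo, hi + 1):
            pep = seq[start - 1 : start - 1 + L]
            if set(pep) & AMBIGUOUS_RESIDUES:
                continue
            offsets = tuple(
                p - start + 1 for p in range(max(a, start), min(b, start + L - 1) + 1)
            )
            wt = wt_window(mut, start, L)
            if pep in by_seq:
                by_seq[pep].sources.append((mut.protein_id, mut.source_variant.key, start))
            else:
                by_seq[pep] = PeptideCandidate(
                    sequence=pep,
                    patient_id=mut.source_variant.patient_id,
                    source_protein=mut.protein_id,
                    source_variant=mut.source_variant,
                    start=start,
                    mut_offsets=offsets,
                    wt_counterpart=wt,
                )
    return list(by_seq.values())


def wt_window(mut: MutatedProtein, start: int, length: int) -> Optional[str]:
    """Same-coordinates wild-type window for an SNV-derived candidate; None for
    indel/frameshift candidates, which have no positional counterpart."""
    if mut.source_variant.var_class != "SNV":
        return None
    wt = mut.wt_sequence[start - 1 : start - 1 + length]
    return wt if len(wt) == length else None


class ProteomeIndex:
    """Exact-substring index over a set of reference proteins.

    Holds one hash set of k-mers per queried peptide length; results are by
    contract identical to a naive per-protein substring scan.
    """

    def __init__(self, sequences: Iterable[str], lengths: Iterable[int]):
        seqs = [s.upper() for s in sequences]
        if not seqs:
            raise ValueError("empty reference proteome set (misconfiguration)")
        self._lengths = sorted(set(lengths))
        self._kmers: dict[int, set[str]] = {L: set() for L in self._lengths}
        for s in seqs:
            for L in self._lengths:
                kmers = self._kmers[L]
                for i in range(len(s) - L + 1):
                    kmers.add(s[i : i + L])

    def contains(self, peptide: str) -> bool:
        peptide = peptide.upper()
        L = len(peptide)
        if L not in self._kmers:
            raise ValueError(f"index not built for length {L}")
        return peptide in self._kmers[L]


def filter_wildtype(
    candidates: Sequence[PeptideCandidate],
    reference_proteomes: Sequence[Iterable[str]],
    lengths: Iterable[int] = range(8, 12),
) -> list[PeptideCandidate]:
    """Exclude candidates occurring as exact substrings of any reference
    protein in any of the supplied proteomes. Adding proteomes is monotone:
    the surviving set can only shrink."""
    if not reference_proteomes:
        raise ValueError("at least one reference proteome is required")
    indexes = [ProteomeIndex(p, lengths) for p in reference_proteomes]
    return [c for c in candidates if not any(ix.contains(c.sequence) for ix in indexes)]


def naive_wildtype_scan(peptide: str, sequences: Iterable[str]) -> bool:
    """Reference implementation: linear substring scan (oracle for the index)."""
    peptide = peptide.upper()
    return any(peptide in s.upper() for s in sequences)
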