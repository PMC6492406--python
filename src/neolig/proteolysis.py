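"""In silico tryptic digestion and mutation-distinguishing peptide enumeration.

Trypsin cleaves C-terminally of lysine and arginine; with the conventional
proline rule a K/R-P bond is not cleaved (the MaxQuant-style "Trypsin/P"
setting disables that exception). A substitution can create or destroy a
cleavage site, which is what makes some mutant peptides detectable as fully
tryptic peptides where the wild type is not — the signal exploited when
hunting mutated peptides in shotgun proteome data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TrypticPeptide:
    """A tryptic peptide with 1-based closed protein coordinates and the number
    of internal K/R sites left uncut (missed cleavages)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    n_term_context: str  # residue preceding the peptide, '-' at protein N-terminus
    c_term_context: str  # residue following the peptide, '-' at protein C-terminus


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices i such that trypsin cuts between sequence[i] and
    sequence[i+1]. The protein C-terminus is not a site."""
    sites = []
    n = len(sequence)
    for i in range(n - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def tryptic_digest(
    sequence: str,
    max_missed: int = 2,
    proline_rule: bool = True,
) -> list[TrypticPeptide]:
    """Enumerate all tryptic peptides with 0..max_missed missed cleavages.

    The zero-missed-cleavage peptides concatenate back to the input exactly.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    sites = cleavage_sites(sequence, proline_rule)
    # fragment boundaries: starts of each fully-cleaved fragment, 0-based
    bounds = [0] + [i + 1 for i in sites] + [len(sequence)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j > n_frag:
                break
            s, e = bounds[i], bounds[j]
            peptides.append(
                TrypticPeptide(
                    sequence=sequence[s:e],
                    start=s + 1,
                    end=e,
                    missed_cleavages=m,
                    n_term_context=sequence[s - 1] if s > 0 else "-",
                    c_term_context=sequence[e] if e < len(sequence) else "-",
                )
            )
    return peptides


@dataclass
class DistinguishingReport:
    """Peptides separating a mutant protein from its wild type at digest level."""

    mutant_unique: set[str]
    wildtype_lost: set[str]
    cleavage_change: bool


def distinguishing_peptides(
    wt_sequence: str,
    mut_sequence: str,
    max_missed: int = 2,
    proline_rule: bool = True,
    ref_aa: Optional[str] = None,
    alt_aa: Optional[str] = None,
) -> DistinguishingReport:
    """Mutant-unique peptides (digest(mut) \\ digest(wt) by sequence), lost
    wild-type peptides, and whether the substitution gains or loses a K/R
    cleavage site (ref in {K,R} xor alt in {K,R}).

    ``ref_aa``/``alt_aa`` drive the cleavage-change flag; when absent it is
    inferred from the first differing residue of equal-length sequences.
    """
    wt_sequence, mut_sequence = wt_sequence.upper(), mut_sequence.upper()
    wt_set = {p.sequence for p in tryptic_digest(wt_sequence, max_missed, proline_rule)} \
        if wt_sequence else set()
    mut_set = {p.sequence for p in tryptic_digest(mut_sequence, max_missed, proline_rule)} \
        if mut_sequence else set()
    if wt_sequence == mut_sequence:
        return DistinguishingReport(set(), set(), False)
    if ref_aa is None or alt_aa is None:
        ref_aa, alt_aa = "", ""
        if len(wt_sequence) == len(mut_sequence):
            for a, b in zip(wt_sequence, mut_sequence):
                if a != b:
                    ref_aa, alt_aa = a, b
                    break
    change = (ref_aa in ("K", "R")) != (alt_aa in ("K", "R"))
    return DistinguishingReport(
        mutant_unique=mut_set - wt_set,
        wildtype_lost=wt_set - mut_set,
        cleavage_change=change,
    )


def annotate_shotgun_evidence(
    candidates: Sequence,
    shotgun_table: pd.DataFrame,
    mutant_peptides_by_variant: Optional[dict] = None,
    min_len: int = 6,
    max_len: int = 30,
) -> None:
    """Attach shotgun-proteome evidence flags (PNE^prot) to candidates.

    Level 1 (``PNE_prot``): some detected tryptic peptide maps to the
    candidate's source protein — evidence that the protein is present, not
    that the mutation is. Level 2 (``PNE_prot_mut``): a mutant-distinguishing
    peptide of the candidate's variant is itself detected. Detected peptides
    outside the [min_len, max_len] detectability window are ignored.
    log2 intensities of supporting peptides are attached as
    ``shotgun_log2_intensities``.
    """
    required = {"peptide", "protein_ids", "intensity"}
    if not required <= set(shotgun_table.columns):
        raise ValueError(f"shotgun table must have columns {sorted(required)}")
    tab = shotgun_table.copy()
    tab["peptide"] = tab["peptide"].str.upper()
    tab = tab[tab["peptide"].str.len().between(min_len, max_len)]

    by_protein: dict[str, list[float]] = {}
    detected_peptides: set[str] = set()
    for _, row in tab.iterrows():
        detected_peptides.add(row["peptide"])
        for pid in str(row["protein_ids"]).split(";"):
            pid = pid.strip()
            if pid:
                by_protein.setdefault(pid, []).append(float(row["intensity"]))

    for cand in candidates:
        intens = by_protein.get(cand.source_protein)
        if intens:
            cand.tier_flags.add("PNE_prot")
            cand.shotgun_log2_intensities = [float(np.log2(x)) if x > 0 else float("-inf")
                                             for x in intens]
        if mutant_peptides_by_variant:
            distinct = mutant_peptides_by_variant.get(cand.source_variant.key, set())
            if distinct & detected_peptides:
                cand.tier_flags.add("PNE_prot_mut")
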