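"""Tryptic digestion, cleavage-site gain/loss, and shotgun evidence flags."""
import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import parser as pyt_parser

from neolig import distinguishing_peptides, tryptic_digest
from neolig.proteolysis import annotate_shotgun_evidence, cleavage_sites

from conftest import make_candidate, make_variant

ALB_WT = "GGRLAKTYETTLEKAAR"   # toy flanking context around the LAK...LEK stretch
ALB_MUT = "GGRLAETYETTLEKAAR"  # K->E substitution removes a cleavage site


def brute_force_digest(seq, max_missed, proline_rule=True):
    """Independent enumeration from first principles: all substrings whose
    boundaries are cleavage boundaries and whose internal site count <= max."""
    cuts = [0] + [i + 1 for i in range(len(seq) - 1)
                  if seq[i] in "KR" and not (proline_rule and seq[i + 1] == "P")] + [len(seq)]
    peps = set()
    for a, b in itertools.combinations(range(len(cuts)), 2):
        internal = b - a - 1
        if internal <= max_missed:
            peps.add(seq[cuts[a]:cuts[b]])
    return peps


def test_simple_rule_application():
    peps = {p.sequence for p in tryptic_digest("MKAR", 0, proline_rule=False)}
    assert peps == {"MK", "AR"}


def test_wildtype_context_yields_missed_cleavage_peptide():
    peps = {p.sequence: p for p in tryptic_digest(ALB_WT, 2)}
    assert "LAKTYETTLEK" in peps
    assert peps["LAKTYETTLEK"].missed_cleavages == 1


def test_mutant_context_swaps_tryptic_peptides():
    peps = {p.sequence: p for p in tryptic_digest(ALB_MUT, 2)}
    assert "LAETYETTLEK" in peps
    assert peps["LAETYETTLEK"].missed_cleavages == 0
    assert "LAKTYETTLEK" not in peps


def test_proline_rule():
    with_rule = {p.sequence for p in tryptic_digest("AKPGGR", 0, proline_rule=True)}
    without = {p.sequence for p in tryptic_digest("AKPGGR", 0, proline_rule=False)}
    assert "AKPGGR" in with_rule and "AK" not in with_rule
    assert {"AK", "PGGR"} <= without


def test_zero_missed_peptides_tile_the_protein():
    seq = "MKAVLRKPQSTRWYK"
    zero = sorted((p for p in tryptic_digest(seq, 2) if p.missed_cleavages == 0),
                  key=lambda p: p.start)
    assert "".join(p.sequence for p in zero) == seq
    for p in zero:
        assert seq[p.start - 1 : p.end] == p.sequence


@given(seq=st.text("ACDKRPST", min_size=1, max_size=40),
       max_missed=st.integers(0, 3))
@settings(max_examples=150, deadline=None)
def test_digest_matches_bruteforce(seq, max_missed):
    got = {p.sequence for p in tryptic_digest(seq, max_missed)}
    assert got == brute_force_digest(seq, max_missed)


def test_digest_matches_pyteomics(rng):
    """Independent oracle: pyteomics' cleavage routine with the same rule."""
    for _ in range(20):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        ours = {p.sequence for p in tryptic_digest(seq, 2, proline_rule=True)}
        theirs = pyt_parser.cleave(seq, r"[KR](?!P)", missed_cleavages=2)
        assert ours == set(theirs)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        tryptic_digest("", 2)


def test_gained_cleavage_site_exposes_mutant_peptide():
    # H->R immediately upstream of AVEIQIQELTER creates a tryptic start
    wt = "GGKAHAVEIQIQELTERKAA"
    mut = "GGKARAVEIQIQELTERKAA"
    rep = distinguishing_peptides(wt, mut, 2)
    assert "AVEIQIQELTER" in rep.mutant_unique
    assert rep.cleavage_change is True
    # fully tryptic in the mutant: preceded by R, ends at R
    frag = {p.sequence: p for p in tryptic_digest(mut, 0)}
    assert "AVEIQIQELTER" in frag


def test_lost_cleavage_site_distinguishes_mutant():
    rep = distinguishing_peptides(ALB_WT, ALB_MUT, 2, ref_aa="K", alt_aa="E")
    assert "LAETYETTLEK" in rep.mutant_unique
    assert "LAKTYETTLEK" in rep.wildtype_lost
    assert rep.cleavage_change is True


def test_identical_sequences_empty_report():
    rep = distinguishing_peptides(ALB_WT, ALB_WT, 2)
    assert rep.mutant_unique == set() and rep.wildtype_lost == set()
    assert rep.cleavage_change is False


def test_distinguishing_symmetry(rng):
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
    mut = seq[:24] + ("R" if seq[24] != "R" else "K") + seq[25:]
    fwd = distinguishing_peptides(seq, mut, 2)
    rev = distinguishing_peptides(mut, seq, 2)
    assert fwd.mutant_unique == rev.wildtype_lost
    assert fwd.wildtype_lost == rev.mutant_unique


def test_shotgun_evidence_levels():
    cand = make_candidate("LAETYETTL", wt="LAKTYETTL")
    other = make_candidate("WWWWWWWW", protein="PROTX",
                           variant=make_variant(protein="PROTX", gpos=2000))
    table = pd.DataFrame({
        "peptide": ["LAETYETTLEK", "SOMEOTHERK"],
        "protein_ids": ["PROT1", "PROTZ"],
        "intensity": [2.0 ** 20, 2.0 ** 18],
    })
    mutant_map = {cand.source_variant.key: {"LAETYETTLEK"}}
    annotate_shotgun_evidence([cand, other], table, mutant_map)
    assert "PNE_prot" in cand.tier_flags
    assert "PNE_prot_mut" in cand.tier_flags
    assert cand.shotgun_log2_intensities == [pytest.approx(20.0)]
    assert other.tier_flags == set()


def test_shotgun_table_validation():
    with pytest.raises(ValueError):
        annotate_shotgun_evidence([], pd.DataFrame({"peptide": []}))
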