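"""Sliding-window search space construction and wild-type exclusion."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neolig import apply_variant, filter_wildtype, generate_windows
from neolig.binding import AMINO_ACIDS
from neolig.pss import ProteomeIndex, naive_wildtype_scan

from conftest import make_candidate, make_variant


def brute_force_windows(seq, a, b, lengths):
    """Independent enumeration: every window of each length overlapping [a, b]."""
    out = set()
    for L in lengths:
        for start in range(1, len(seq) - L + 2):
            if start <= b and start + L - 1 >= a:
                out.add(seq[start - 1 : start - 1 + L])
    return out


def _mut(seq, pos, alt):
    v = make_variant(pos=pos, ref_aa=seq[pos - 1], alt_aa=alt)
    return apply_variant(seq, v)


def test_interior_snv_yields_38_windows(rng):
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
    mut = _mut(seq, 30, "W" if seq[29] != "W" else "Y")
    wins = generate_windows(mut, range(8, 12))
    # closed form: sum of lengths 8+9+10+11, assuming no duplicate sequences
    assert len(wins) == 38
    assert {w.sequence for w in wins} == brute_force_windows(
        mut.mut_sequence, 30, 30, range(8, 12))


def test_snv_near_nterm_clipped():
    seq = "ACDEFGHIKLMNPQRSTVWY" * 2
    mut = _mut(seq, 2, "W")
    wins = generate_windows(mut, [9])
    assert len(wins) == 2
    starts = sorted(w.start for w in wins)
    assert starts == [1, 2]


def test_every_window_overlaps_affected_position(rng):
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
    mut = _mut(seq, 17, "W" if seq[16] != "W" else "Y")
    for w in generate_windows(mut, range(8, 12)):
        assert w.start <= 17 <= w.start + w.length - 1
        assert w.sequence[17 - w.start] == mut.mut_sequence[16]


def test_frameshift_tail_windows_match_bruteforce(rng):
    # mutant with a 12-residue novel C-terminal tail
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
    from neolig.mutanome import MutatedProtein
    tail = "".join(rng.choice(list(AMINO_ACIDS), size=12))
    mut = MutatedProtein(
        protein_id="PROT1", wt_sequence=seq,
        mut_sequence=seq[:30] + tail, affected_start=31,
        affected_end=42, source_variant=make_variant(),
    )
    wins = generate_windows(mut, [9])
    expected = brute_force_windows(mut.mut_sequence, 31, 42, [9])
    assert {w.sequence for w in wins} == expected


def test_random_positions_match_bruteforce(rng):
    """1,000 random (protein, position) draws, including terminus clipping."""
    for _ in range(1000):
        n = int(rng.integers(12, 80))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        pos = int(rng.integers(2, n))
        alt = AMINO_ACIDS[int(rng.integers(20))]
        if alt == seq[pos - 1]:
            alt = "W" if seq[pos - 1] != "W" else "Y"
        mut = _mut(seq, pos, alt)
        wins = generate_windows(mut, range(8, 12))
        assert {w.sequence for w in wins} == brute_force_windows(
            mut.mut_sequence, pos, pos, range(8, 12))


def test_wt_counterpart_revert():
    seq = "GGRLAKTYETTLEKAARXXLLLQQQ".replace("X", "S")
    mut = _mut(seq, 6, "E")
    wins = generate_windows(mut, [11])
    for w in wins:
        assert w.wt_counterpart is not None
        i = 6 - w.start  # offset of the substituted residue in the window
        assert w.wt_counterpart[:i] == w.sequence[:i]
        assert w.wt_counterpart[i] == "K" and w.sequence[i] == "E"


def test_frameshift_candidates_have_no_counterpart(rng):
    from neolig.mutanome import MutatedProtein
    from neolig.variants import Variant
    fs_var = Variant("P1", "chr1", 9, "AT", "A", gene="PROT1", protein_id="PROT1")
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
    mut = MutatedProtein("PROT1", seq, seq[:20] + "WWWWWWWWWWWW", 21, 32, fs_var)
    assert all(w.wt_counterpart is None for w in generate_windows(mut, [9]))


def test_filter_wildtype_removes_reference_substrings():
    ref = ["MMMMACDEFGHIKMMMM"]
    contained = make_candidate("ACDEFGHIK")
    novel = make_candidate("ACDEFGHIW")
    out = filter_wildtype([contained, novel], [ref], [9])
    assert [c.sequence for c in out] == ["ACDEFGHIW"]


def test_filter_wildtype_monotone(rng):
    peps = [make_candidate("".join(rng.choice(list(AMINO_ACIDS), size=9)))
            for _ in range(50)]
    ref1 = ["".join(rng.choice(list(AMINO_ACIDS), size=200)) for _ in range(5)]
    ref2 = [p.sequence for p in peps[:10]]
    kept_one = {c.sequence for c in filter_wildtype(peps, [ref1], [9])}
    kept_two = {c.sequence for c in filter_wildtype(peps, [ref1, ref2], [9])}
    assert kept_two <= kept_one


def test_index_equals_naive_scan(rng):
    proteome = ["".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(50, 300))))
                for _ in range(200)]
    index = ProteomeIndex(proteome, range(8, 12))
    # mix of planted substrings and random peptides
    queries = []
    for _ in range(250):
        s = proteome[int(rng.integers(len(proteome)))]
        L = int(rng.integers(8, 12))
        start = int(rng.integers(0, len(s) - L + 1))
        queries.append(s[start : start + L])
    for _ in range(250):
        L = int(rng.integers(8, 12))
        queries.append("".join(rng.choice(list(AMINO_ACIDS), size=L)))
    for q in queries:
        assert index.contains(q) == naive_wildtype_scan(q, proteome)


def test_empty_proteome_rejected():
    with pytest.raises(ValueError):
        ProteomeIndex([], [9])
    with pytest.raises(ValueError):
        filter_wildtype([make_candidate("ACDEFGHIK")], [], [9])
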