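"""Variant classification, expression evidence, TMB, and cohort recurrence."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neolig import classify_variant, compute_tmb, is_expressed, recurrence_analysis
from neolig.variants import ProteinChange, Variant

from conftest import make_variant


@pytest.mark.parametrize(
    "ref,alt,pc,expected_class,expected_ns",
    [
        ("A", "T", ProteinChange(375, "K", "E"), "SNV", True),
        ("A", "T", ProteinChange(10, "L", "L"), "SNV", False),
        ("AT", "A", None, "frameshift", True),          # 1-nt deletion shifts frame
        ("A", "ATTT", ProteinChange(3, "K", "KF"), "insertion", True),
        ("AGGG", "A", ProteinChange(3, "KF", "K"), "deletion", True),
        ("A", "AT", None, "frameshift", True),
        ("C", "G", None, "SNV", False),                 # unannotated -> synonymous
    ],
)
def test_classification(ref, alt, pc, expected_class, expected_ns):
    var_class, ns = classify_variant(ref, alt, pc)
    assert var_class == expected_class
    assert ns is expected_ns


def test_classification_rejects_non_dna():
    with pytest.raises(ValueError):
        classify_variant("AX", "A", None)
    with pytest.raises(ValueError):
        classify_variant("", "A", None)


@given(ref=st.text("ACGT", min_size=1, max_size=6),
       alt=st.text("ACGT", min_size=1, max_size=6))
@settings(max_examples=200, deadline=None)
def test_classification_is_a_partition(ref, alt):
    var_class, _ = classify_variant(ref, alt, None)
    assert var_class in ("SNV", "insertion", "deletion", "frameshift")


def test_expression_rule():
    v = make_variant(rna_alt_depth=5, rna_depth=30, fpkm=3.2)
    assert is_expressed(v)
    assert not is_expressed(make_variant(rna_alt_depth=0, rna_depth=30, fpkm=10.0))
    assert not is_expressed(make_variant(rna_alt_depth=4, rna_depth=30, fpkm=0.0))
    assert not is_expressed(v, min_alt_reads=6)
    with pytest.raises(ValueError):
        is_expressed(v, min_alt_reads=-1)


def test_expression_requires_nonsynonymous():
    v = Variant("P1", "chr1", 5, "A", "G")  # no protein change
    with pytest.raises(ValueError):
        is_expressed(v)


def test_tmb_division():
    assert compute_tmb(70, 35) == pytest.approx(2.0)
    assert compute_tmb(0, 35) == 0.0
    # a cohort-mean 66 Var^ns over a 35 Mb callable exome sits near 1.9/Mb
    assert compute_tmb(66, 35) == pytest.approx(1.886, abs=1e-3)
    with pytest.raises(ValueError):
        compute_tmb(10, 0)


@given(n=st.integers(0, 10_000), mb=st.floats(0.1, 100), c=st.floats(1.1, 10))
@settings(max_examples=100, deadline=None)
def test_tmb_linearity(n, mb, c):
    assert compute_tmb(2 * n, mb) == pytest.approx(2 * compute_tmb(n, mb))
    assert compute_tmb(n, mb * c) == pytest.approx(compute_tmb(n, mb) / c)


def test_recurrence_identical_variant_in_three_patients():
    cohort = [
        make_variant(patient=f"HCC{i:03d}", protein="NBPF1", gpos=16891365)
        for i in (1, 2, 3)
    ] + [make_variant(patient="HCC001", protein="OTHER", gpos=999)]
    rep = recurrence_analysis(cohort, min_patients=3)
    assert list(rep.shared_genes["gene"]) == ["NBPF1"]
    rec = rep.recurrent_variants
    assert len(rec) == 1
    assert rec.loc[0, "pos"] == 16891365 and rec.loc[0, "n_patients"] == 3


def test_recurrence_single_patient_shares_nothing():
    cohort = [make_variant(patient="P1", gpos=i) for i in range(1, 6)]
    rep = recurrence_analysis(cohort, min_patients=3)
    assert rep.shared_genes.empty and rep.recurrent_variants.empty


def test_recurrence_matches_bruteforce(rng):
    cohort = [
        make_variant(patient=f"P{rng.integers(8)}", protein=f"G{rng.integers(10)}",
                     gpos=int(rng.integers(1, 20)))
        for _ in range(200)
    ]
    rep = recurrence_analysis(cohort, min_patients=2)
    # brute force gene-level tally
    tally = {}
    for v in cohort:
        tally.setdefault(v.gene, set()).add(v.patient_id)
    expected = {g for g, ps in tally.items() if len(ps) >= 2}
    assert set(rep.shared_genes["gene"]) == expected
    pos_tally = {}
    for v in cohort:
        pos_tally.setdefault(v.key, set()).add(v.patient_id)
    expected_pos = {k for k, ps in pos_tally.items() if len(ps) >= 2}
    got = {(r.chrom, r.pos, r.ref, r.alt) for r in rep.recurrent_variants.itertuples()}
    assert got == expected_pos
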