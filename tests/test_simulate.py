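"""Synthetic cohort generator: determinism, distributional contracts, planting."""
import numpy as np
import pandas as pd
import pytest

from neolig import (SyntheticCohortConfig, generate_cohort, generate_ligandome,
                    generate_patient, generate_proteome, generate_shotgun)
from neolig.binding import AMINO_ACIDS
from neolig.proteolysis import tryptic_digest


def test_proteome_shape_and_determinism():
    cfg = SyntheticCohortConfig(proteome_size=10, protein_length_mean=300, seed=1)
    a = generate_proteome(cfg)
    b = generate_proteome(cfg)
    assert a == b
    assert len(a) == 10
    assert len({rid for rid, _ in a}) == 10
    for _, seq in a:
        assert seq == seq.upper() and set(seq) <= set(AMINO_ACIDS)
        assert len(seq) >= 30


def test_proteome_seed_sensitivity():
    a = generate_proteome(SyntheticCohortConfig(proteome_size=5, seed=1))
    b = generate_proteome(SyntheticCohortConfig(proteome_size=5, seed=2))
    assert {s for _, s in a} != {s for _, s in b}


def test_empty_proteome_rejected():
    with pytest.raises(ValueError):
        SyntheticCohortConfig(proteome_size=0)


def test_config_validates_proportions():
    with pytest.raises(ValueError):
        SyntheticCohortConfig(rna_evidence_rate=1.2)
    with pytest.raises(ValueError):
        SyntheticCohortConfig(ligand_shared_fraction=-0.1)


def test_patient_variant_count_matches_expectation():
    """Monte-Carlo mean of Var^ns against the closed form tmb_mean x callable Mb."""
    cfg = SyntheticCohortConfig(tmb_mean=1.89, tmb_sd=0.49, nonsyn_fraction=0.44,
                                callable_region_mb=35.0, proteome_size=50, seed=3)
    proteome = generate_proteome(cfg)
    counts = []
    for i in range(200):
        variants, _ = generate_patient(cfg, proteome, seed=1000 + i)
        counts.append(sum(v.is_nonsynonymous for v in variants))
    mean = np.mean(counts)
    expected = 1.89 * 35.0  # ~66
    # SE includes Poisson and TMB-draw variance components
    se = np.sqrt((expected + (0.49 * 35.0) ** 2) / 200)
    assert abs(mean - expected) < 3 * se


@pytest.mark.parametrize("rate,check", [
    (0.0, lambda nexp, nns: nexp == 0),
    (1.0, lambda nexp, nns: nexp == nns),
])
def test_rna_evidence_rate_extremes(rate, check):
    cfg = SyntheticCohortConfig(rna_evidence_rate=rate, proteome_size=30, seed=5)
    proteome = generate_proteome(cfg)
    variants, _ = generate_patient(cfg, proteome, seed=11)
    ns = [v for v in variants if v.is_nonsynonymous]
    nexp = sum(v.rna_alt_depth >= 1 and v.fpkm > 0 for v in ns)
    assert check(nexp, len(ns))


def test_rna_evidence_rate_converges():
    """Observed Var^exp fraction at rate 0.44 sits in the binomial 99% CI."""
    cfg = SyntheticCohortConfig(rna_evidence_rate=0.44, proteome_size=50, seed=9)
    proteome = generate_proteome(cfg)
    n_ns = n_exp = 0
    seed = 0
    while n_ns < 1000:
        variants, _ = generate_patient(cfg, proteome, seed=7000 + seed)
        seed += 1
        for v in variants:
            if v.is_nonsynonymous:
                n_ns += 1
                n_exp += int(v.rna_alt_depth >= 1 and v.fpkm > 0)
    frac = n_exp / n_ns
    half_width = 2.576 * np.sqrt(0.44 * 0.56 / n_ns)
    assert abs(frac - 0.44) < half_width


def test_ligandome_planting_rules(rng):
    cfg = SyntheticCohortConfig(proteome_size=30, ligand_list_size_mean=120,
                                ligand_list_size_sd=10, seed=2)
    proteome = generate_proteome(cfg)
    planted_ne = ["WWWWYYYYK", "FFFFWWWWHH"]
    planted_wt = ["MMMMYYYYK"]
    tumor, normal = generate_ligandome("P1", proteome, planted_ne, planted_wt,
                                       cfg, rng)
    assert set(planted_ne) <= tumor.peptides
    assert set(planted_wt) <= tumor.peptides
    assert not set(planted_ne) & normal.peptides
    planted_records = [r for r in tumor.records if r.peptide in planted_ne]
    assert all(r.q_value == 0.01 for r in planted_records)
    assert all(0 <= r.q_value <= 1 for r in tumor.records + normal.records)


def test_ligandome_rejects_bad_planted_length(rng):
    cfg = SyntheticCohortConfig(proteome_size=30, seed=2)
    proteome = generate_proteome(cfg)
    with pytest.raises(ValueError):
        generate_ligandome("P1", proteome, ["SHORT"], [], cfg, rng)


def test_ligandome_shared_fraction(rng):
    """Empirical tumor/normal overlap tracks the configured shared fraction."""
    cfg = SyntheticCohortConfig(proteome_size=100, ligand_list_size_mean=2000,
                                ligand_list_size_sd=1, ligand_shared_fraction=0.5,
                                seed=2)
    proteome = generate_proteome(cfg)
    tumor, normal = generate_ligandome("P1", proteome, [], [], cfg, rng,
                                       contaminant_fraction=0.0)
    inter = len(tumor.peptides & normal.peptides)
    frac = inter / len(tumor.peptides)
    assert abs(frac - 0.5) < 0.05


def test_shotgun_peptides_are_tryptic(small_cohort):
    """Cross-module check: every emitted shotgun peptide is a valid tryptic
    peptide (<=2 missed cleavages) of its stated source protein or mutanome."""
    proteome = dict(small_cohort.proteome)
    for patient in small_cohort.patients:
        mutant_peps = small_cohort.truth.shotgun_mutant_peptides[patient.patient_id]
        for row in patient.shotgun.itertuples():
            if row.peptide in mutant_peps:
                continue
            digest = {p.sequence for p in tryptic_digest(proteome[row.protein_ids], 2)}
            assert row.peptide in digest


def test_shotgun_coverage_zero_empty():
    cfg = SyntheticCohortConfig(proteome_size=20, shotgun_coverage_rate=0.0, seed=4)
    proteome = generate_proteome(cfg)
    df, covered, muts = generate_shotgun("P1", proteome, [], cfg,
                                         np.random.default_rng(1))
    assert df.empty and covered == set() and muts == set()


def test_cohort_determinism(tmp_path):
    from neolig import write_cohort
    cfg = SyntheticCohortConfig(n_patients=1, proteome_size=40,
                                ligand_list_size_mean=60, ligand_list_size_sd=5,
                                seed=13)
    a, b = generate_cohort(cfg), generate_cohort(cfg)
    write_cohort(a, tmp_path / "a")
    write_cohort(b, tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_planted_truth_consistency(small_cohort):
    for patient in small_cohort.patients:
        planted = small_cohort.truth.planted_nelig[patient.patient_id]
        assert planted <= patient.tumor_ligandome.peptides
        assert not planted & patient.normal_ligandome.peptides
        for pep in planted:
            assert 8 <= len(pep) <= 11
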