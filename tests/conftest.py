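import numpy as np
import pytest

from neolig import (PipelineConfig, SyntheticCohortConfig, ProteinChange, Variant,
                    generate_cohort, random_matrix_set)
from neolig.pss import PeptideCandidate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrices(rng):
    return random_matrix_set(["A*01:01", "B*08:01"], range(8, 12), rng)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SyntheticCohortConfig(
        n_patients=2, proteome_size=60, ligand_list_size_mean=100,
        ligand_list_size_sd=20, planted_nelig_per_patient=2,
        planted_wtlig_per_patient=1, seed=7,
    )
    return generate_cohort(cfg)


def make_variant(patient="P1", pos=5, ref_aa="K", alt_aa="E", protein="PROT1",
                 gpos=1000, **kw):
    return Variant(
        patient_id=patient, chrom="chr1", genomic_pos=gpos, ref_allele="A",
        alt_allele="G", gene=protein, protein_id=protein,
        protein_change=ProteinChange(protein_pos=pos, ref_aa=ref_aa, alt_aa=alt_aa),
        **kw,
    )


def make_candidate(seq, wt=None, patient="P1", protein="PROT1", mut_offset=1,
                   variant=None):
    return PeptideCandidate(
        sequence=seq, patient_id=patient, source_protein=protein,
        source_variant=variant or make_variant(patient=patient, protein=protein),
        start=1, mut_offsets=(mut_offset,), wt_counterpart=wt,
    )


@pytest.fixture
def pipeline_config():
    return PipelineConfig()
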