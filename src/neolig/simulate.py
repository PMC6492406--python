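"""Synthetic cohort generator with known ground truth.

Emulates the data layers of a tumor neoepitope study — a reference proteome,
per-patient somatic variant tables at a configurable tumor mutational burden,
RNA-level evidence labels, tumor and non-malignant eluted-ligand lists with
planted mutated (NE^lig) and wild-type (WT^lig) ligands, and tryptic shotgun
peptide tables — so that every pipeline stage can be exercised end to end
and its outputs checked against planted truth. Default parameters describe a
low-TMB liver-cancer-like cohort (~1.9 variants/Mb over a 35 Mb callable
exome, ~44% of non-synonymous variants with RNA evidence).

Planted NE^lig are forced to pass the built-in binder filter and the
wild-type exclusion filter by rejection sampling over alternate residues, so
downstream recovery tests exercise the tier logic rather than the scorer.
Fixed seed implies byte-identical cohort artifacts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding import AMINO_ACIDS, MatrixSet, matrix_to_frame, predict_binders, random_matrix_set
from .config import SyntheticCohortConfig
from .io import write_fasta, write_ligand_tsv, write_variant_tsv
from .ligandome import LigandomeSample, LigandRecord
from .mutanome import MutatedProtein, apply_variant
from .proteolysis import distinguishing_peptides, tryptic_digest
from .pss import filter_wildtype, generate_windows
from .variants import ProteinChange, Variant

_ALLELE_POOL = [
    "A*01:01", "A*02:01", "A*03:01", "A*24:02", "A*26:01", "B*07:02",
    "B*08:01", "B*44:03", "B*51:01", "C*04:01", "C*07:01", "C*07:02",
]


@dataclass
class GroundTruth:
    """Planted truth for one cohort, keyed by patient."""

    planted_nelig: dict[str, set[str]] = field(default_factory=dict)
    planted_wtlig: dict[str, set[str]] = field(default_factory=dict)
    rna_evidence: dict[str, dict[str, bool]] = field(default_factory=dict)
    shotgun_proteins: dict[str, set[str]] = field(default_factory=dict)
    shotgun_mutant_peptides: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(d):
            return {k: sorted(v) if isinstance(v, set) else v for k, v in sorted(d.items())}
        payload = {
            "planted_nelig": enc(self.planted_nelig),
            "planted_wtlig": enc(self.planted_wtlig),
            "rna_evidence": {p: dict(sorted(m.items())) for p, m in sorted(self.rna_evidence.items())},
            "shotgun_proteins": enc(self.shotgun_proteins),
            "shotgun_mutant_peptides": enc(self.shotgun_mutant_peptides),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class PatientBundle:
    patient_id: str
    alleles: list[str]
    variants: list[Variant]
    tumor_ligandome: LigandomeSample
    normal_ligandome: LigandomeSample
    shotgun: pd.DataFrame


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    proteome: list[tuple[str, str]]
    matrices: MatrixSet
    patients: list[PatientBundle]
    truth: GroundTruth


def generate_proteome(config: SyntheticCohortConfig,
                      rng: Optional[np.random.Generator] = None) -> list[tuple[str, str]]:
    """Random reference proteome: uppercase 20-letter sequences with unique IDs."""
    if config.proteome_size < 1:
        raise ValueError("proteome_size must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(config.proteome_size):
        length = max(config.min_protein_length,
                     int(round(rng.normal(config.protein_length_mean, config.protein_length_sd))))
        seq = "".join(rng.choice(aa, size=length))
        records.append((f"SYNP{i + 1:05d}", seq))
    return records


def _draw_variant(patient_id: str, proteome: Sequence[tuple[str, str]],
                  rng: np.random.Generator, nonsyn: bool, pos_pool: set[int]) -> Variant:
    idx = int(rng.integers(len(proteome)))
    pid, seq = proteome[idx]
    # interior positions only: no positional model is assumed beyond uniformity
    ppos = int(rng.integers(2, len(seq)))
    ref_aa = seq[ppos - 1]
    if nonsyn:
        alt_aa = ref_aa
        while alt_aa == ref_aa:
            alt_aa = AMINO_ACIDS[int(rng.integers(20))]
    else:
        alt_aa = ref_aa
    gpos = int(rng.integers(1, 10_000_000))
    while gpos in pos_pool:
        gpos = int(rng.integers(1, 10_000_000))
    pos_pool.add(gpos)
    bases = "ACGT"
    ref_b = bases[int(rng.integers(4))]
    alt_b = ref_b
    while alt_b == ref_b:
        alt_b = bases[int(rng.integers(4))]
    return Variant(
        patient_id=patient_id, chrom=f"chr{idx % 22 + 1}", genomic_pos=gpos,
        ref_allele=ref_b, alt_allele=alt_b, gene=pid, transcript_id=f"{pid}.t1",
        protein_id=pid,
        protein_change=ProteinChange(protein_pos=ppos, ref_aa=ref_aa, alt_aa=alt_aa),
    )


def _attach_rna(variant: Variant, expressed: bool, rng: np.random.Generator) -> None:
    if expressed:
        variant.rna_alt_depth = 1 + int(rng.poisson(15))
        variant.rna_depth = variant.rna_alt_depth + int(rng.poisson(25))
        variant.fpkm = float(np.round(rng.lognormal(1.5, 1.0), 3)) + 0.001
    else:
        variant.rna_alt_depth = 0
        variant.rna_depth = int(rng.poisson(25))
        variant.fpkm = float(np.round(rng.lognormal(0.5, 1.0), 3)) if rng.random() < 0.5 else 0.0


def _plant_binder_candidate(
    variant: Variant,
    proteome: Sequence[tuple[str, str]],
    matrices: MatrixSet,
    alleles: Sequence[str],
    rng: np.random.Generator,
    length_range: range = range(8, 12),
    max_tries: int = 200,
):
    """Rejection-sample the variant's alternate residue until one of its
    search-space windows passes both the wild-type exclusion and the binder
    filter; returns (candidate, mutated_protein)."""
    sequences = [s for _, s in proteome]
    wt_seq = next(s for pid, s in proteome if pid == variant.protein_id)
    for _ in range(max_tries):
        mut = apply_variant(wt_seq, variant)
        windows = generate_windows(mut, length_range)
        surviving = filter_wildtype(windows, [sequences], length_range)
        pne = predict_binders(surviving, list(alleles), matrices)
        if pne:
            choice = pne[int(rng.integers(len(pne)))]
            return choice, mut
        pc = variant.protein_change
        alt = pc.ref_aa
        while alt == pc.ref_aa:
            alt = AMINO_ACIDS[int(rng.integers(20))]
        variant.protein_change = ProteinChange(pc.protein_pos, pc.ref_aa, alt)
    raise RuntimeError("could not plant a binder-passing candidate; "
                       "matrices may be degenerate")


def _background_windows(proteome: Sequence[tuple[str, str]], n: int,
                        rng: np.random.Generator, length_range: range) -> list[str]:
    """Wild-type proteome windows used as background eluted ligands; being
    reference substrings, they can never masquerade as mutated ligands."""
    lengths = list(length_range)
    out = []
    for _ in range(n):
        _, seq = proteome[int(rng.integers(len(proteome)))]
        L = lengths[int(rng.integers(len(lengths)))]
        start = int(rng.integers(0, len(seq) - L + 1))
        out.append(seq[start : start + L])
    return out


def generate_patient(
    config: SyntheticCohortConfig,
    proteome: Sequence[tuple[str, str]],
    seed: int,
    patient_id: str = "P001",
) -> tuple[list[Variant], GroundTruth]:
    """Somatic variant table for one patient plus its RNA-evidence truth.

    The expected total variant count is tmb_mean / nonsyn_fraction x
    callable_region_mb (Poisson-distributed around a patient-level TMB draw);
    each variant is non-synonymous with probability nonsyn_fraction, and
    non-synonymous variants carry RNA evidence i.i.d. at rna_evidence_rate.
    """
    if not proteome:
        raise ValueError("proteome must be nonempty")
    rng = np.random.default_rng([seed, 1])
    tmb = max(0.0, rng.normal(config.tmb_mean, config.tmb_sd))
    lam = (tmb / config.nonsyn_fraction if config.nonsyn_fraction > 0 else tmb) \
        * config.callable_region_mb
    n_var = int(rng.poisson(lam))
    pos_pool: set[int] = set()
    variants, rna_labels = [], {}
    for _ in range(n_var):
        nonsyn = bool(rng.random() < config.nonsyn_fraction)
        v = _draw_variant(patient_id, proteome, rng, nonsyn, pos_pool)
        if nonsyn:
            expressed = bool(rng.random() < config.rna_evidence_rate)
            _attach_rna(v, expressed, rng)
            rna_labels[str(v.key)] = expressed
        variants.append(v)
    truth = GroundTruth(rna_evidence={patient_id: rna_labels})
    return variants, truth


def generate_ligandome(
    patient_id: str,
    proteome: Sequence[tuple[str, str]],
    planted_nelig: Sequence[str],
    planted_wtlig: Sequence[str],
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    contaminant_fraction: float = 0.1,
) -> tuple[LigandomeSample, LigandomeSample]:
    """Tumor and non-malignant eluted-ligand lists.

    Planted mutated and wild-type ligands appear in the tumor list at
    q = 0.01; the non-malignant list never contains a planted mutated ligand.
    Background ligands are wild-type proteome windows; a configurable shared
    fraction of the tumor background also appears in the normal background.
    Low-confidence contaminants get q in (0.05, 0.5] and are removed by the
    standard 5% FDR filter.
    """
    length_range = range(8, 12)
    for pep in list(planted_nelig) + list(planted_wtlig):
        if not 8 <= len(pep) <= 11:
            raise ValueError(f"planted peptide outside 8-11 length range: {pep}")
    n_list = max(len(planted_nelig) + len(planted_wtlig) + 10,
                 int(round(rng.normal(config.ligand_list_size_mean, config.ligand_list_size_sd))))
    n_background = n_list - len(planted_nelig) - len(planted_wtlig)
    n_shared = int(round(config.ligand_shared_fraction * n_background))
    shared = _background_windows(proteome, n_shared, rng, length_range)
    tumor_private = _background_windows(proteome, n_background - n_shared, rng, length_range)
    normal_private = _background_windows(proteome, n_background - n_shared, rng, length_range)

    def records(peps: Sequence[str], planted: bool) -> list[LigandRecord]:
        out = []
        for p in peps:
            if planted:
                q = 0.01
            elif rng.random() < contaminant_fraction:
                q = float(np.round(0.05 + rng.random() * 0.45, 4)) + 1e-4
            else:
                q = float(np.round(rng.random() * 0.05, 4))
            src = tuple(pid for pid, s in proteome if p in s)[:3] or ("unknown",)
            out.append(LigandRecord(peptide=p, q_value=min(q, 1.0), source_protein_ids=src))
        return out

    tumor = LigandomeSample(patient_id, "tumor",
                            records(list(planted_nelig) + list(planted_wtlig), True)
                            + records(shared + tumor_private, False))
    normal = LigandomeSample(patient_id, "non_malignant",
                             records(shared + normal_private, False))
    return tumor, normal


def generate_shotgun(
    patient_id: str,
    proteome: Sequence[tuple[str, str]],
    mutanome: Sequence[MutatedProtein],
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    include_mutant_for: Sequence = (),
    max_missed: int = 2,
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Tryptic shotgun peptide table.

    Proteins are covered i.i.d. at shotgun_coverage_rate; covered proteins
    contribute a handful of detectable tryptic peptides (6-30 residues,
    <=2 missed cleavages). For variants listed in ``include_mutant_for`` a
    mutant-distinguishing tryptic peptide is emitted as well. Returns the
    table plus ground-truth covered-protein and mutant-peptide sets.
    """
    rows, covered, mutant_peps = [], set(), set()
    for pid, seq in proteome:
        if rng.random() >= config.shotgun_coverage_rate:
            continue
        covered.add(pid)
        peps = [p for p in tryptic_digest(seq, max_missed)
                if 6 <= len(p.sequence) <= 30]
        if not peps:
            continue
        k = min(len(peps), 1 + int(rng.poisson(3)))
        for i in sorted(rng.choice(len(peps), size=k, replace=False)):
            rows.append({"peptide": peps[i].sequence, "protein_ids": pid,
                         "intensity": float(np.round(rng.lognormal(20, 2), 1)),
                         "sample": patient_id})
    wanted = {v.key for v in include_mutant_for}
    for mp in mutanome:
        if mp.source_variant.key not in wanted:
            continue
        rep = distinguishing_peptides(mp.wt_sequence, mp.mut_sequence, max_missed)
        usable = sorted(p for p in rep.mutant_unique if 6 <= len(p) <= 30)
        if usable:
            pep = usable[int(rng.integers(len(usable)))]
            mutant_peps.add(pep)
            covered.add(mp.protein_id)
            rows.append({"peptide": pep, "protein_ids": mp.protein_id,
                         "intensity": float(np.round(rng.lognormal(20, 2), 1)),
                         "sample": patient_id})
    df = pd.DataFrame(rows, columns=["peptide", "protein_ids", "intensity", "sample"])
    return df, covered, mutant_peps


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Full synthetic cohort: proteome, binding matrices, per-patient variant
    tables, ligandomes with planted truth, and shotgun tables."""
    root_rng = np.random.default_rng(config.seed)
    proteome = generate_proteome(config, root_rng)
    matrices = random_matrix_set(_ALLELE_POOL, range(8, 12), root_rng)
    truth = GroundTruth()
    patients = []
    for i in range(config.n_patients):
        patient_id = f"SYN{i + 1:03d}"
        prng = np.random.default_rng([config.seed, 100 + i])
        alleles = sorted(prng.choice(_ALLELE_POOL, size=config.n_alleles, replace=False))
        variants, ptruth = generate_patient(config, proteome, int(prng.integers(2**31)),
                                            patient_id)
        truth.rna_evidence[patient_id] = ptruth.rna_evidence[patient_id]

        # choose expressed non-synonymous SNVs to host planted ligands
        expressed = [v for v in variants if v.is_nonsynonymous and v.rna_alt_depth > 0
                     and v.fpkm > 0 and v.var_class == "SNV"]
        n_plant = config.planted_nelig_per_patient + config.planted_wtlig_per_patient
        while len(expressed) < n_plant:
            pos_pool = {v.genomic_pos for v in variants}
            v = _draw_variant(patient_id, proteome, prng, True, pos_pool)
            _attach_rna(v, True, prng)
            truth.rna_evidence[patient_id][str(v.key)] = True
            variants.append(v)
            expressed.append(v)
        hosts = [expressed[j] for j in prng.choice(len(expressed), size=n_plant, replace=False)] \
            if n_plant else []

        planted_ne, planted_wt, mutanome = [], [], []
        for j, host in enumerate(hosts):
            cand, mut = _plant_binder_candidate(host, proteome, matrices, alleles, prng)
            mutanome.append(mut)
            if j < config.planted_nelig_per_patient:
                planted_ne.append(cand.sequence)
            else:
                # plant only the wild-type counterpart: mutated ligand stays absent
                wt = cand.wt_counterpart
                if wt is not None:
                    planted_wt.append(wt)
        truth.planted_nelig[patient_id] = set(planted_ne)
        truth.planted_wtlig[patient_id] = set(planted_wt)

        tumor, normal = generate_ligandome(patient_id, proteome, planted_ne, planted_wt,
                                           config, prng)
        shotgun, covered, mut_peps = generate_shotgun(
            patient_id, proteome, mutanome, config, prng,
            include_mutant_for=[m.source_variant for m in mutanome[:1]],
        )
        truth.shotgun_proteins[patient_id] = covered
        truth.shotgun_mutant_peptides[patient_id] = mut_peps
        patients.append(PatientBundle(patient_id, list(alleles), variants, tumor,
                                      normal, shotgun))
    return SyntheticCohort(config, proteome, matrices, patients, truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Persist all cohort artifacts (FASTA, TSV dialects, JSON truth sidecar,
    matrix fixtures, per-patient allele table). Deterministic given the seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.proteome, out / "proteome.fasta")
    all_variants = [v for p in cohort.patients for v in p.variants]
    write_variant_tsv(all_variants, out / "variants.tsv")
    write_ligand_tsv([s for p in cohort.patients
                      for s in (p.tumor_ligandome, p.normal_ligandome)],
                     out / "ligands.tsv")
    shotgun = pd.concat([p.shotgun for p in cohort.patients], ignore_index=True) \
        if cohort.patients else pd.DataFrame(columns=["peptide", "protein_ids",
                                                      "intensity", "sample"])
    shotgun.to_csv(out / "shotgun.tsv", sep="\t", index=False)
    pd.DataFrame([{"patient": p.patient_id, "alleles": ";".join(p.alleles)}
                  for p in cohort.patients]).to_csv(out / "alleles.tsv", sep="\t", index=False)
    mats = []
    for allele in cohort.matrices.alleles():
        for L in range(8, 12):
            m = cohort.matrices.get(allele, L)
            if m is not None:
                df = matrix_to_frame(m)
                df.insert(0, "allele", allele)
                df.insert(1, "length", L)
                mats.append(df)
    pd.concat(mats, ignore_index=True).to_csv(out / "matrices.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(cohort.truth.to_json())
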