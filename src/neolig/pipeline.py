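"""End-to-end pipeline driver: variants -> mutanome -> peptide search space ->
HLA-binding filter -> evidence tiers -> prioritization, with every stage's
output persisted as headered TSV for auditability."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .binding import MatrixSet, binder_fraction, predict_binders
from .config import PipelineConfig
from .evidence import (TierSummary, annotate_ligandome_tier, annotate_rna_tier,
                       summaries_to_frame, summarize_tiers)
from .liganddb import LigandDatabase, prioritize_pne
from .ligandome import LigandomeSample, filter_ligands, overlap_fraction
from .mutanome import AnnotationMismatchError, apply_variant
from .proteolysis import annotate_shotgun_evidence, distinguishing_peptides
from .pss import PeptideCandidate, filter_wildtype, generate_windows
from .stats import CohortReport
from .variants import Variant

log = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """In-memory inputs for one cohort run."""

    proteome: list[tuple[str, str]]
    variants: list[Variant]
    alleles_by_patient: dict[str, list[str]]
    matrices: MatrixSet
    ligandomes: list[LigandomeSample] = field(default_factory=list)
    shotgun: Optional[pd.DataFrame] = None
    ligand_db: Optional[LigandDatabase] = None
    extra_proteomes: list[list[str]] = field(default_factory=list)


@dataclass
class PatientResult:
    patient_id: str
    candidates: list[PeptideCandidate]
    summary: TierSummary
    prioritized: Optional[pd.DataFrame] = None
    tumor_binder_fraction: Optional[float] = None
    tumor_normal_overlap: Optional[float] = None


@dataclass
class PipelineResult:
    patients: list[PatientResult]
    report: CohortReport

    @property
    def summaries(self) -> pd.DataFrame:
        return summaries_to_frame([p.summary for p in self.patients])


def build_candidates(
    patient_variants: Sequence[Variant],
    proteome_by_id: dict[str, str],
    config: PipelineConfig,
) -> tuple[list[PeptideCandidate], dict]:
    """Mutanome + sliding windows for one patient, deduplicated by sequence
    across proteins; returns candidates plus mutant-distinguishing tryptic
    peptides per variant (for shotgun-level evidence)."""
    by_seq: dict[str, PeptideCandidate] = {}
    mutant_peptides: dict = {}
    for v in patient_variants:
        if not v.is_nonsynonymous:
            continue
        wt = proteome_by_id.get(v.protein_id)
        if wt is None:
            log.warning("variant %s: protein %s absent from proteome; skipped",
                        v.key, v.protein_id)
            continue
        if v.var_class == "frameshift":
            log.warning("variant %s: frameshift without CDS; skipped", v.key)
            continue
        try:
            mut = apply_variant(wt, v)
        except AnnotationMismatchError as e:
            log.warning("%s", e)
            continue
        if mut is None:
            continue
        rep = distinguishing_peptides(mut.wt_sequence, mut.mut_sequence,
                                      config.max_missed_cleavages, config.proline_rule)
        mutant_peptides[v.key] = {
            p for p in rep.mutant_unique
            if config.shotgun_min_len <= len(p) <= config.shotgun_max_len
        }
        for cand in generate_windows(mut, config.length_range):
            if cand.sequence in by_seq:
                by_seq[cand.sequence].sources.extend(cand.sources)
            else:
                by_seq[cand.sequence] = cand
    return list(by_seq.values()), mutant_peptides


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run every stage for every patient; deterministic given fixed inputs."""
    proteome_by_id = dict(inputs.proteome)
    reference_sets = [[s for _, s in inputs.proteome]] + list(inputs.extra_proteomes)
    ligandomes_by_patient: dict[str, list[LigandomeSample]] = {}
    for s in inputs.ligandomes:
        filtered = filter_ligands(s, config.q_threshold,
                                  (config.min_length, config.max_length))
        ligandomes_by_patient.setdefault(s.patient_id, []).append(filtered)

    patient_ids = sorted({v.patient_id for v in inputs.variants}
                         | set(inputs.alleles_by_patient))
    results = []
    for pid in patient_ids:
        pvars = [v for v in inputs.variants if v.patient_id == pid]
        alleles = inputs.alleles_by_patient.get(pid, [])
        candidates, mutant_peps = build_candidates(pvars, proteome_by_id, config)
        candidates = filter_wildtype(candidates, reference_sets, config.length_range) \
            if candidates else []
        predict_binders(candidates, alleles, inputs.matrices, config.binder_threshold)
        annotate_rna_tier(candidates, config.min_alt_reads, config.min_fpkm)
        if inputs.shotgun is not None and len(inputs.shotgun):
            sub = inputs.shotgun[inputs.shotgun["sample"].astype(str) == pid] \
                if "sample" in inputs.shotgun.columns else inputs.shotgun
            annotate_shotgun_evidence(candidates, sub, mutant_peps,
                                      config.shotgun_min_len, config.shotgun_max_len)
        samples = ligandomes_by_patient.get(pid, [])
        if samples:
            annotate_ligandome_tier(candidates, samples, config.il_equivalent)
        summary = summarize_tiers(pid, pvars, candidates,
                                  config.min_alt_reads, config.min_fpkm)
        log.info("patient %s waterfall: Var=%d Var_ns=%d Var_exp=%d PSS=%d PNE=%d "
                 "PNE_exp=%d PNE_prot=%d NE_lig=%d", pid, summary.n_var,
                 summary.n_var_ns, summary.n_var_exp, summary.n_pss, summary.n_pne,
                 summary.n_pne_exp, summary.n_pne_prot, summary.n_ne_lig)
        res = PatientResult(pid, candidates, summary)
        tumor = next((s for s in samples if s.tissue == "tumor"), None)
        normal = next((s for s in samples if s.tissue == "non_malignant"), None)
        if tumor is not None:
            res.tumor_binder_fraction = binder_fraction(
                sorted(tumor.peptides), alleles, inputs.matrices, config.binder_threshold)
        if tumor is not None and normal is not None:
            res.tumor_normal_overlap = overlap_fraction(tumor, normal, mode="tumor")
        if inputs.ligand_db is not None:
            pne = [c for c in candidates if "PNE" in c.tier_flags]
            res.prioritized = prioritize_pne(pne, inputs.ligand_db)
        results.append(res)

    report = CohortReport(summaries=[r.summary for r in results],
                          callable_region_mb=config.callable_region_mb,
                          settings=config.to_dict())
    out = PipelineResult(patients=results, report=report)
    if outdir is not None:
        persist_outputs(out, Path(outdir), config)
    return out


def candidates_to_frame(patients: Sequence[PatientResult]) -> pd.DataFrame:
    rows = []
    for p in patients:
        for c in sorted(p.candidates, key=lambda c: c.sequence):
            rows.append({
                "patient": p.patient_id, "peptide": c.sequence, "length": c.length,
                "source_protein": c.source_protein,
                "variant": "|".join(map(str, c.source_variant.key)),
                "mut_offsets": ";".join(map(str, c.mut_offsets)),
                "wt_counterpart": c.wt_counterpart or "",
                "tiers": ";".join(sorted(c.tier_flags)),
                "best_relative_score": max((r.relative_score for r in c.binding_records),
                                           default=float("nan")),
            })
    return pd.DataFrame(rows, columns=["patient", "peptide", "length", "source_protein",
                                       "variant", "mut_offsets", "wt_counterpart",
                                       "tiers", "best_relative_score"])


def persist_outputs(result: PipelineResult, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.summaries.to_csv(outdir / "tier_summaries.tsv", sep="\t", index=False)
    candidates_to_frame(result.patients).to_csv(outdir / "candidates.tsv",
                                                sep="\t", index=False)
    result.report.tier_stats().to_csv(outdir / "cohort_tiers.tsv", sep="\t", index=False)
    extras = []
    for p in result.patients:
        extras.append({
            "patient": p.patient_id,
            "tumor_binder_fraction": "" if p.tumor_binder_fraction is None
            else round(p.tumor_binder_fraction, 6),
            "tumor_normal_overlap": "" if p.tumor_normal_overlap is None
            else round(p.tumor_normal_overlap, 6),
        })
        if p.prioritized is not None:
            p.prioritized.to_csv(outdir / f"prioritized_{p.patient_id}.tsv",
                                 sep="\t", index=False)
    pd.DataFrame(extras).to_csv(outdir / "ligandome_metrics.tsv", sep="\t", index=False)
    config.to_yaml(str(outdir / "config_used.yaml"))
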