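"""Readers/writers for the pipeline's file dialects.

Formats: FASTA (proteomes / mutanomes, via Biopython), VCF 4.2 (via pysam,
using an ANN/CSQ-style annotation field when present), and documented
tab-separated dialects for variant, ligand, shotgun, ligand-database and
CTA tables. All intermediate artifacts are headered TSV so every stage is
auditable. All positions are 1-based, intervals closed.

Variant TSV columns: patient, chrom, pos, ref, alt, gene, transcript,
protein_id, protein_pos, ref_aa, alt_aa, rna_depth, rna_alt_depth, fpkm
(protein_id optional; falls back to gene).
Ligand TSV: patient, tissue, peptide, q, accessions (";"-joined).
Shotgun TSV: peptide, protein_ids, intensity, sample.
Ligand-database TSV: peptide, sample_id.
CTA list TSV: accession, antigen, family.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ligandome import LigandomeSample, LigandRecord
from .variants import ProteinChange, Variant

PathLike = Union[str, Path]

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*", "Sec": "U",
}
_HGVS_P = re.compile(r"p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|fs.*|\*)?")


class DialectError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path: PathLike) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------- variants

_VARIANT_COLS = ["patient", "chrom", "pos", "ref", "alt", "gene", "transcript",
                 "protein_id", "protein_pos", "ref_aa", "alt_aa",
                 "rna_depth", "rna_alt_depth", "fpkm"]


def read_variant_tsv(path: PathLike) -> list[Variant]:
    df = _read_tsv(path)
    required = {"patient", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise DialectError(f"{path}: missing variant columns {sorted(missing)}")
    variants = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            pc = None
            if _present(row.get("protein_pos")):
                pc = ProteinChange(
                    protein_pos=int(row["protein_pos"]),
                    ref_aa=_str(row, "ref_aa"),
                    alt_aa=_str(row, "alt_aa"),
                )
            variants.append(Variant(
                patient_id=str(row["patient"]),
                chrom=str(row["chrom"]),
                genomic_pos=int(row["pos"]),
                ref_allele=str(row["ref"]).upper(),
                alt_allele=str(row["alt"]).upper(),
                gene=_str(row, "gene"),
                transcript_id=_str(row, "transcript"),
                protein_id=_str(row, "protein_id") or _str(row, "gene"),
                protein_change=pc,
                rna_depth=int(_num(row, "rna_depth")),
                rna_alt_depth=int(_num(row, "rna_alt_depth")),
                fpkm=float(_num(row, "fpkm")),
            ))
        except (ValueError, KeyError) as e:
            raise DialectError(f"{path}, line {line}: {e}") from e
    return variants


def write_variant_tsv(variants: Sequence[Variant], path: PathLike) -> None:
    rows = []
    for v in variants:
        pc = v.protein_change
        rows.append({
            "patient": v.patient_id, "chrom": v.chrom, "pos": v.genomic_pos,
            "ref": v.ref_allele, "alt": v.alt_allele, "gene": v.gene,
            "transcript": v.transcript_id, "protein_id": v.protein_id,
            "protein_pos": pc.protein_pos if pc else "",
            "ref_aa": pc.ref_aa if pc else "", "alt_aa": pc.alt_aa if pc else "",
            "rna_depth": v.rna_depth, "rna_alt_depth": v.rna_alt_depth,
            "fpkm": v.fpkm,
        })
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False)


def parse_hgvs_p(hgvs: str) -> Optional[ProteinChange]:
    """Parse a protein HGVS like p.Lys375Glu (3-letter codes) into a
    ProteinChange; frameshift notations (p.Xxx123fs) yield an empty alt."""
    m = _HGVS_P.match(hgvs.strip())
    if not m:
        return None
    ref3, pos, alt = m.group(1), int(m.group(2)), m.group(3) or ""
    ref1 = _AA3TO1.get(ref3)
    if ref1 is None:
        return None
    if alt.startswith("fs") or alt == "":
        alt1 = ""
    elif alt == "*":
        alt1 = "*"
    else:
        alt1 = _AA3TO1.get(alt, "")
    return ProteinChange(protein_pos=pos, ref_aa=ref1, alt_aa=alt1)


def read_vcf(path: PathLike, patient_id: str) -> list[Variant]:
    """Read a VCF 4.2 file, using a SnpEff-style ANN annotation field when
    present (fields: allele|effect|impact|gene|gene_id|feature_type|
    transcript|...|HGVS.c|HGVS.p|...). Positions stay 1-based. Files without
    annotation yield variants with no protein change; use the variant TSV
    dialect to supply annotation instead."""
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                gene = transcript = ""
                pc = None
                ann = rec.info.get("ANN") if "ANN" in (rec.info or {}) else None
                if ann:
                    entries = ann if isinstance(ann, (tuple, list)) else [ann]
                    for entry in entries:
                        parts = str(entry).split("|")
                        if parts and parts[0] == alt:
                            gene = parts[3] if len(parts) > 3 else ""
                            transcript = parts[6] if len(parts) > 6 else ""
                            if len(parts) > 10 and parts[10]:
                                pc = parse_hgvs_p(parts[10])
                            break
                variants.append(Variant(
                    patient_id=patient_id, chrom=str(rec.chrom),
                    genomic_pos=int(rec.pos), ref_allele=str(rec.ref).upper(),
                    alt_allele=str(alt).upper(), gene=gene,
                    transcript_id=transcript, protein_id=gene,
                    protein_change=pc,
                ))
    return variants


# ---------------------------------------------------------------- ligands

def read_ligand_tsv(path: PathLike) -> list[LigandomeSample]:
    df = _read_tsv(path)
    required = {"patient", "tissue", "peptide", "q"}
    missing = required - set(df.columns)
    if missing:
        raise DialectError(f"{path}: missing ligand columns {sorted(missing)}")
    samples: dict[tuple[str, str], LigandomeSample] = {}
    for i, row in df.iterrows():
        try:
            key = (str(row["patient"]), str(row["tissue"]))
            sample = samples.setdefault(key, LigandomeSample(key[0], key[1]))
            accs = tuple(a for a in str(row.get("accessions", "") or "").split(";") if a)
            sample.records.append(LigandRecord(
                peptide=str(row["peptide"]), q_value=float(row["q"]),
                source_protein_ids=accs,
            ))
        except ValueError as e:
            raise DialectError(f"{path}, line {i + 2}: {e}") from e
    return list(samples.values())


def write_ligand_tsv(samples: Sequence[LigandomeSample], path: PathLike) -> None:
    rows = [
        {"patient": s.patient_id, "tissue": s.tissue, "peptide": r.peptide,
         "q": r.q_value, "accessions": ";".join(r.source_protein_ids)}
        for s in samples for r in s.records
    ]
    pd.DataFrame(rows, columns=["patient", "tissue", "peptide", "q", "accessions"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- tables

def read_shotgun_tsv(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"peptide", "protein_ids", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise DialectError(f"{path}: missing shotgun columns {sorted(missing)}")
    return df


def read_cta_tsv(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    if not {"accession", "antigen"} <= set(df.columns):
        raise DialectError(f"{path}: CTA list needs accession and antigen columns")
    return df


def read_ligand_db_tsv(path: PathLike):
    from .liganddb import LigandDatabase
    return LigandDatabase.from_frame(_read_tsv(path))


def _read_tsv(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                           na_values=[""]).convert_dtypes()
    except pd.errors.ParserError as e:
        raise DialectError(f"{path}: {e}") from e


def _present(value) -> bool:
    return value is not None and not pd.isna(value) and str(value) != ""


def _str(row, col: str) -> str:
    v = row.get(col)
    return str(v) if _present(v) else ""


def _num(row, col: str) -> float:
    v = row.get(col)
    return float(v) if _present(v) else 0.0
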