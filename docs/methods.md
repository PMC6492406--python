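# Methods

## Scope and model

`neolig` models the evidence chain from somatic variants to HLA class I
neoepitope candidates as a strict narrowing of peptide sets:

    Var ⊇ Var_ns ⊇ Var_exp        (variant level)
    PSS ⊇ PNE ⊇ {PNE_exp, PNE_prot, NE_lig}   (peptide level)

All peptide-level matching is case-normalized exact string equality. An
optional I/L-equivalent mode exists for MS-facing comparisons (leucine and
isoleucine are isobaric and indistinguishable by conventional fragmentation),
but it is off by default because database matching in this workflow is
defined as exact matching.

## Variant layer

A variant is an SNV iff both alleles have length 1; an indel is a frameshift
iff its length difference is not divisible by 3; these four classes (SNV,
insertion, deletion, frameshift) partition all inputs. A variant is
non-synonymous iff it is a frameshift or its annotated protein change alters
the residue.

RNA-level evidence (`Var_exp`) requires both an alt-supporting RNA read
count and transcript expression. The default rule is ≥ 1 alt-supporting
read and FPKM > 0. Both thresholds are configurable
(`min_alt_reads`, `min_fpkm`); the defaults are deliberately permissive
because the two signals individually are noisy and the tier is meant as a
plausibility filter, not a quantification.

Tumor mutational burden is `Var_ns / callable_region_mb`. The default
callable exome size is 35 Mb, consistent with whole-exome callable regions
after standard filtering; it is configurable and only affects the TMB scale,
never the peptide logic. Variants in HLA genes (symbol starting `HLA-`) are
flagged as potential artifacts of the polymorphic locus but never excluded.

Coordinates are 1-based with closed intervals throughout (genomic and
protein).

## Mutanome

SNVs and in-frame indels are applied at protein level after verifying that
the annotated reference residue matches the supplied sequence (a mismatch
raises, signalling annotation/proteome incoherence). Frameshifts require the
CDS and the 1-based CDS position of the edit; the mutant tail is translated
with the standard genetic code to the first stop codon (stop excluded), and
the affected interval runs from the first altered residue to the new
C-terminus — every residue of the tail is non-template relative to wild
type, so all of it seeds search-space windows. A frameshift whose first
altered codon is a stop contributes no novel residues and is dropped with a
warning, as are stop-gain SNVs (truncation creates no mutant windows).
Ambiguous residues (U/B/Z/X) in references are tolerated, but windows
containing them are dropped.

The personalized search database is the reference proteome plus one record
per mutated protein with the stable header `<protein_id>|<patient>|<change>`.

## Peptide search space

For each window length L in 8–11, every L-window of the mutant sequence
overlapping the affected interval is emitted, clipped to sequence bounds.
An interior SNV therefore yields exactly 8+9+10+11 = 38 windows; clipping at
the termini only reduces the count. Duplicate sequences within a patient are
stored once with multi-source bookkeeping (unique-peptide counting), and
deduplication happens before binding prediction.

Wild-type exclusion removes every candidate occurring as an exact substring
of any supplied reference proteome. The implementation indexes all k-mers of
the queried lengths in hash sets; its contract — verified in tests — is
result-identity with a naive per-protein substring scan. The filter is
monotone: adding reference proteomes never enlarges the surviving set.

The wild-type counterpart of an SNV-derived candidate is the
same-coordinates window of the wild-type sequence. Indel- and
frameshift-derived candidates have no positional counterpart and none is
assigned.

## HLA binding

The built-in scorer is an additive position-weight matrix per (allele,
length): score = Σ per-position residue weights, normalized by the maximum
attainable sum, binder iff relative score ≥ 0.5. The half-max threshold is a
heuristic in the tradition of additive-matrix epitope predictors and is
configurable. A peptide is a PNE when it binds ≥ 1 of the patient's (up to
six, homozygote-deduplicated) alleles — the any-allele rule, with
all-allele/majority consensus left to the caller by adjusting the input
allele set. Matrices used in tests and simulations are seeded synthetic
fixtures with anchor-position structure, not published motif matrices;
adapters for external affinity predictors (binder iff %rank ≤ 2.0) satisfy
the same record contract but are never required.

## Proteolysis

Trypsin cleaves C-terminally of K/R; by default the proline rule suppresses
cleavage of K/R–P bonds (conventional specificity; a Trypsin/P mode disables
the exception). Digestion enumerates all peptides with 0–2 missed cleavages
(configurable). Zero-missed-cleavage peptides tile the protein exactly;
tests verify the enumeration against brute force and against an independent
cleavage routine. Mutant-distinguishing peptides are the set difference
digest(mutant) \ digest(wild type) by sequence; the cleavage-change flag is
set iff exactly one of (ref, alt) is K/R. No mass or hydrophobicity model is
applied; shotgun matching restricts to 6–30 residues as a typical
detectability window.

Shotgun evidence is two-level: level 1 (`PNE_prot`, the headline count) —
any detected tryptic peptide maps to the candidate's source protein;
level 2 (`PNE_prot_mut`) — a mutant-distinguishing peptide itself is
detected. Level 1 is deliberately weak evidence (presence of the protein,
not the mutation) and is reported as such.

## Ligandome layer

Eluted-ligand lists are filtered at q ≤ 0.05 and length 8–11, deduplicating
identical peptides to their best q (the filter is idempotent). `NE_lig`
requires the mutated sequence in the patient's tumor list; `WT_lig` matches
the wild-type counterpart in either tissue and records the tissue label,
since wild-type presentation in either compartment supports processability
of the site. Tumor/normal overlap is reported as |T∩N|/|T| by default with
|T∩N|/|T∪N| available; the tumor-denominator convention makes the number
directly interpretable as "fraction of tumor ligands also seen in normal
tissue".

The CTA screen annotates ligands whose source accession appears in a
catalogue of cancer-testis antigens; antigen counting collapses family
members (e.g. the SSX paralogues) via an explicit family column, because a
multi-mapping peptide within one family is evidence for one antigen, not
several.

## Background-database prioritization

The wild-type ligand database maps peptide → set of observing samples;
a query counts distinct samples (monotone under database growth).
Candidates are ranked by descending WT-ligand match count — the heuristic
being that a frequently presented wild-type window demonstrates efficient
processing and presentation of that protein region, raising the prior that
the mutated counterpart can be presented too. The sort is stable (ties keep
input order); an order-invariant tie-break by binding score then lexicographic
peptide is available as an option. Candidates without a wild-type
counterpart (indel/frameshift-derived) rank last with an absent count.

## Synthetic cohort generator

The generator emulates a low-burden hepatocellular-carcinoma-like cohort;
its defaults are the study conditions for all tests:

| parameter | default | meaning |
|---|---|---|
| tmb_mean ± tmb_sd | 1.89 ± 0.49 /Mb | patient-level TMB draw |
| callable_region_mb | 35 | callable exome size |
| nonsyn_fraction | 0.44 | P(variant is non-synonymous) |
| rna_evidence_rate | 0.44 | P(Var_ns has RNA evidence) |
| planted_nelig / wtlig per patient | 2 / 1 | ground-truth ligands |
| ligand_list_size_mean ± sd | 300 ± 60 | eluted peptides per tissue |
| ligand_shared_fraction | 0.5 | tumor/normal background sharing |
| shotgun_coverage_rate | 0.3 | P(protein detected in shotgun) |

The expected total variant count is (tmb_mean / nonsyn_fraction) ×
callable_region_mb (Poisson around the patient TMB draw), so ~150 variants
and ~66 non-synonymous ones per patient. Variant positions are uniform over
protein interiors (no positional or signature model). Real deep
immunopeptidome datasets reach ~1400 peptides per tissue; the default list
size of 300 keeps simulated cohorts fast, and the planting/recovery logic is
independent of list size (callers wanting realistic list sizes set
`ligand_list_size_mean=1403, ligand_list_size_sd=621`).

Planted mutated ligands are forced through the actual wild-type-exclusion
and binder filters by rejection sampling over the alternate residue, so
recovery tests exercise tier logic rather than scorer behaviour. Planted
peptides get q = 0.01; a ~10% contaminant fraction gets q in (0.05, 0.5]
and is removed by the standard FDR filter. Background ligands are wild-type
proteome windows — by construction they can never appear as false mutated
ligands, which makes the zero-false-positive assertion exact rather than
probabilistic. The tumor/normal sharing model draws a common background pool
of the configured fraction; this overlap-generating process is a modeling
choice, not an inference from data, and the post-filter overlap reported by
the pipeline sits slightly below the configured raw fraction because
contaminant removal thins both lists independently.

What the generator does **not** emulate: mutational signatures, read-level
noise, spectral-level identification errors, HLA allotype-specific ligand
motifs in the background lists, shared peptides between patients, and
expression-dependent presentation bias. Passing recovery tests therefore
demonstrates correctness of the pipeline's set logic and bookkeeping on
idealized inputs, not calibration of identification rates on real data.

## Numerical and reporting choices

- Sample standard deviation (n−1) for all "mean ± SD" reporting.
- TMB category fractions use strict `>` at each threshold.
- Pearson correlation via the standard product-moment estimator; undefined
  (absent with a warning) under zero variance, and requiring ≥ 3 pairs.
- Empty ligand lists yield an absent binder fraction, never 0.
- All randomness flows through numpy Generators seeded from a single
  configuration seed; fixed seed ⇒ byte-identical artifacts.
- Problem sizes in tests and in `scripts/acceptance.py` (cohorts of 1–2
  patients over 40–60 protein proteomes, 200 patients for variant-layer
  statistics, a 50,000-entry database fixture) are chosen so the full suite
  runs in well under a minute while keeping every distributional check
  adequately powered; all scale parameters are plain configuration.

## Known limitations

- The built-in matrix scorer is a structural stand-in for trained predictors;
  its absolute binder calls carry no affinity calibration (no nM or %rank
  semantics).
- Frameshift handling requires a caller-supplied CDS; transcript isoform
  selection and multi-transcript collapsing are out of scope (one designated
  transcript per variant, peptide-level deduplication downstream).
- Proteasomal processing, TAP transport, retention time and spectral scoring
  are not modeled.
- The cohort-level statistics module computes, but cannot validate against,
  consortium-scale category fractions: those depend on external datasets
  that are not shipped.
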