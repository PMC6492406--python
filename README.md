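# neolig

Multi-omics identification and prioritization of tumor neoepitopes.

`neolig` implements a proteogenomic pipeline for finding mutation-derived
HLA class I peptide candidates and grading them by the strength of their
experimental evidence. It is aimed at cancer immunogenomics researchers who
have per-patient somatic variant calls, RNA expression, shotgun proteome
peptide tables and/or eluted HLA-ligand (immunopeptidome) lists, and want a
single auditable path from variants to a ranked candidate list.

## The method

Starting from non-synonymous somatic variants (Var<sup>ns</sup>), the
pipeline:

1. applies each protein-level consequence to the reference protein to build
   the patient **mutanome** (SNVs, in-frame indels, frameshifts translated
   from the CDS to the first stop);
2. constructs the **peptide search space (PSS)**: every 8–11mer window
   sliding over the affected mutated positions, excluding any peptide that
   occurs as an exact substring of a reference proteome (so every candidate
   is genuinely mutant);
3. filters the PSS to **predicted neoepitopes (PNE)** with an additive
   position-weight-matrix HLA-binding scorer over up to six patient alleles
   (relative score ≥ 0.5 by default; external predictors plug in via a
   rank-based adapter);
4. attaches evidence tiers: **PNE<sup>exp</sup>** when the source variant
   has RNA-level support (alt-supporting reads and FPKM > 0),
   **PNE<sup>prot</sup>** when shotgun proteomics detects the source protein
   (or a mutant-distinguishing tryptic peptide — substitutions that create
   or destroy a K/R cleavage site are tracked explicitly), and
   **NE<sup>lig</sup>** when the mutated peptide itself is found in the
   patient's tumor HLA ligandome (5% FDR, lengths 8–11);
5. ranks candidates by how often the corresponding wild-type ligand
   (**WT<sup>lig</sup>**) has been observed across a background database of
   eluted HLA ligands, each containing sample counting as one match;
6. reports per-patient tier waterfalls, cohort statistics (mean ± SD per
   tier, Pearson correlations, tumor mutational burden categories), and a
   cancer-testis antigen screen of the ligandome.

A fully synthetic cohort generator (`neolig.simulate`) produces a random
proteome, variant tables at a configurable TMB, ligand lists with planted
NE<sup>lig</sup>/WT<sup>lig</sup>, and tryptic shotgun tables with known
ground truth, so the complete pipeline is testable without any external
data.

## Worked example

```python
import pandas as pd
from neolig import (PipelineConfig, SyntheticCohortConfig, generate_cohort,
                    run_pipeline)
from neolig.pipeline import PipelineInputs

cfg = SyntheticCohortConfig(n_patients=2, proteome_size=60,
                            ligand_list_size_mean=150, ligand_list_size_sd=20,
                            seed=42)
cohort = generate_cohort(cfg)
inputs = PipelineInputs(
    proteome=cohort.proteome,
    variants=[v for p in cohort.patients for v in p.variants],
    alleles_by_patient={p.patient_id: p.alleles for p in cohort.patients},
    matrices=cohort.matrices,
    ligandomes=[s for p in cohort.patients
                for s in (p.tumor_ligandome, p.normal_ligandome)],
    shotgun=pd.concat([p.shotgun for p in cohort.patients], ignore_index=True),
)
res = run_pipeline(PipelineConfig(), inputs)
print(res.summaries.to_string(index=False))
```

prints the per-patient evidence waterfall:

```
patient  Var  Var_ns  Var_exp  PSS  PNE  PNE_exp  PNE_prot  NE_lig
 SYN001  179      86       38 3268 1580      704       224       2
 SYN002  185      89       35 3267 1660      644       575       2
```

Each row narrows from all somatic variants (`Var`) through protein-altering
ones (`Var_ns`), RNA-supported ones (`Var_exp`), the mutated peptide search
space (`PSS`), predicted HLA binders (`PNE`) and their RNA/protein-supported
subsets, down to mutated peptides actually eluted from the tumor HLA
ligandome (`NE_lig`) — here exactly the two planted per patient
(`cohort.truth.planted_nelig`), recovered with no false positives.

Cleavage-site genetics at the digest level:

```python
from neolig import distinguishing_peptides
rep = distinguishing_peptides("GGRLAKTYETTLEKAAR", "GGRLAETYETTLEKAAR",
                              ref_aa="K", alt_aa="E")
# rep.mutant_unique contains 'LAETYETTLEK'; rep.cleavage_change is True
```

The K→E substitution destroys a tryptic cleavage site, so the mutant
peptide `LAETYETTLEK` appears with zero missed cleavages where the wild
type needed one — the signature that makes such mutations directly
observable in shotgun data.

The same stages are available from the shell:

```bash
neolig simulate --seed 3 --outdir cohort/
neolig run --indir cohort/ --outdir results/
neolig digest --fasta proteins.fasta --out peptides.tsv
neolig dbmatch --db wt_ligands.tsv --peptides candidates.tsv --out ranked.tsv
```

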