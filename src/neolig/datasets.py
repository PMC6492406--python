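"""Bundled example data.

``cta_catalog`` maps cancer-testis antigen accessions to antigen names and
family labels (the SSX paralogues collapse to one family-level antigen).
``hcc_cta_ligands`` is a small eluted-ligand table of CTA-derived HLA class I
ligands observed in hepatocellular carcinoma tissue, with the published
peptide-to-accession assignments carried as input annotations.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_cta_tsv, read_ligand_tsv
from .ligandome import LigandomeSample


def _data_path(name: str):
    return resources.files("neolig.data").joinpath(name)


def cta_catalog() -> pd.DataFrame:
    """CTA accession -> antigen name and family."""
    with resources.as_file(_data_path("cta_catalog.tsv")) as p:
        return read_cta_tsv(p)


def hcc_cta_ligands() -> list[LigandomeSample]:
    """CTA-derived HLA class I ligands from HCC tumor tissue."""
    with resources.as_file(_data_path("hcc_cta_ligands.tsv")) as p:
        return read_ligand_tsv(p)
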