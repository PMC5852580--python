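"""Bundled published data for the pumpkin glutathione S-transferase family.

Two small tables transcribed from the published genome-database report of
the *Cucurbita maxima* GST family are shipped with the package so the
duplication and dating analyses run out of the box:

* gene-model coordinates (id, chromosome, start, end, strand) for the 32
  family members — note that CmaGSTT2 is listed on the "00" scaffold with
  the same coordinates as CmaGSTU5, exactly as printed; the reader does
  not repair published conflicts;
* the 16 called duplicate pairs with their published Ks and Ka estimates
  (the underlying sequences are not deposited, so rates cannot be
  recomputed from scratch — the printed values are inputs).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import FamilyTable, read_gene_table


def _data_path(name: str):
    return resources.files("genefam").joinpath("data", name)


def cmagst_coordinates() -> FamilyTable:
    """The published pumpkin GST gene-model coordinate table."""
    with resources.as_file(_data_path("cmagst_coordinates.tsv")) as p:
        return read_gene_table(p)


def cmagst_duplicate_pairs() -> pd.DataFrame:
    """The published duplicate pairs with their Ks and Ka estimates."""
    with resources.as_file(_data_path("cmagst_duplicate_pairs.tsv")) as p:
        return pd.read_csv(p, sep="\t")
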